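"""Line profiles through sphere centres and apparent-size estimation.

A line profile is the image sampled by trilinear interpolation along a
segment through a sphere centre (the transaxial left-right axis by
default, since the spheres are coplanar).  The apparent size of a
sphere is the full width at half maximum of its background-subtracted
profile; plotted against true diameter this gives the spatial-
resolution curve, whose ideal is the identity line.  Small spheres sit
above the identity line once the system resolution, not the object,
sets the profile width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .core import Volume
from .phantom import PhantomSpec, background_mask, sphere_masks


@dataclass
class LineProfile:
    """Samples along a segment: positions (mm, relative to the sphere
    centre, strictly increasing) and image values; the normalization
    applied is recorded, never implicit."""

    positions_mm: np.ndarray
    values: np.ndarray
    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    normalization: str = "raw"   # raw | true-concentration | global-max

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("profile positions must be strictly increasing")

    def normalized(self, reference: float, label: str = "true-concentration"
                   ) -> "LineProfile":
        if reference == 0:
            raise ValueError("zero normalization reference")
        return LineProfile(self.positions_mm, self.values / reference,
                           self.center, self.axis, label)

    @property
    def max(self) -> float:
        return float(self.values.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_mm": self.positions_mm, "value": self.values})


def line_profile(image: Volume, center: tuple[float, float, float],
                 axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
                 half_length_mm: float = 40.0,
                 step_mm: float | None = None) -> LineProfile:
    """Sample the image along center +/- k*step*axis (trilinear).

    The default step is half the smallest voxel spacing.  Raises if the
    segment leaves the volume.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    if step_mm is None:
        step_mm = min(image.grid.spacing) / 2.0
    n = int(np.floor(half_length_mm / step_mm))
    pos = step_mm * np.arange(-n, n + 1)
    points = np.asarray(center)[None, :] + pos[:, None] * axis[None, :]
    idx = image.grid.world_to_index(points)
    hi = np.asarray(image.grid.shape) - 1
    if (idx < 0).any() or (idx > hi).any():
        raise ValueError("profile segment exits the volume; shorten half_length")
    vals = map_coordinates(image.values, idx.T, order=1, mode="nearest")
    return LineProfile(pos, vals, tuple(center), tuple(axis))


class UndefinedFWHMError(ValueError):
    """The profile never rises above the half-maximum level."""


def fwhm(profile: LineProfile, baseline: float = 0.0) -> float:
    """Full width at half maximum of (value - baseline), the crossings
    located by linear interpolation; outermost crossings win ties."""
    v = profile.values - baseline
    peak = v.max()
    if peak <= 0:
        raise UndefinedFWHMError("profile peak does not exceed the baseline")
    half = peak / 2.0
    above = v >= half
    if not above.any() or above.all():
        raise UndefinedFWHMError("no half-maximum crossing inside the profile")
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    p = profile.positions_mm

    def _cross(ia, ib):
        # linear interpolation between the bracketing samples
        if v[ib] == v[ia]:
            return p[ib]
        t = (half - v[ia]) / (v[ib] - v[ia])
        return p[ia] + t * (p[ib] - p[ia])

    left = p[i0] if i0 == 0 else _cross(i0 - 1, i0)
    right = p[i1] if i1 == len(p) - 1 else _cross(i1 + 1, i1)
    return float(right - left)


@dataclass
class ResolutionCurve:
    """Apparent size (profile FWHM, mm) vs true diameter per sphere,
    with the identity line as the ideal; ``flagged`` marks spheres whose
    apparent size deviates from identity by more than the threshold."""

    diameters_mm: np.ndarray
    apparent_mm: np.ndarray
    deviation_threshold: float = 0.25
    profiles: list[LineProfile] = field(default_factory=list)

    @property
    def flagged(self) -> np.ndarray:
        dev = np.abs(self.apparent_mm - self.diameters_mm) / self.diameters_mm
        return dev > self.deviation_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"diameter_mm": self.diameters_mm,
                             "apparent_size_mm": self.apparent_mm,
                             "flagged": self.flagged})


def sphere_profiles(image: Volume, spec: PhantomSpec,
                    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
                    pad_mm: float = 25.0,
                    step_mm: float | None = None) -> dict[float, LineProfile]:
    """One profile per sphere (keyed by diameter), long enough to reach
    background on both sides."""
    out = {}
    for s in spec.spheres:
        out[s.diameter] = line_profile(image, s.center, axis,
                                       half_length_mm=s.radius + pad_mm,
                                       step_mm=step_mm)
    return out


def resolution_curve(image: Volume, spec: PhantomSpec,
                     axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
                     deviation_threshold: float = 0.25,
                     baseline: float | str = "auto") -> ResolutionCurve:
    """Apparent size per sphere from a cold-background image.

    ``baseline`` is subtracted before the half-maximum search: "auto"
    estimates it as the background-VOI mean (and warns if that mean is
    not small against the spheres — the curve is defined for cold
    scans).
    """
    masks = sphere_masks(spec, image.grid)
    if baseline == "auto":
        bg = background_mask(spec, image.grid, sphere_margin=10.0)
        baseline = image.mean_over(bg)
        peak = max(image.mean_over(m) for m in masks)
        if peak > 0 and baseline > 0.05 * peak:
            warnings.warn("background is warm; the resolution-vs-diameter curve "
                          "is defined for cold-background scans", UserWarning)
    profs, apparent = [], []
    for s in spec.spheres:
        prof = line_profile(image, s.center, axis, half_length_mm=s.radius + 25.0)
        profs.append(prof)
        apparent.append(fwhm(prof, baseline=float(baseline)))
    return ResolutionCurve(np.asarray(spec.diameters), np.asarray(apparent),
                           deviation_threshold, profs)


def max_relative_intensity_difference(profiles: dict[float, LineProfile],
                                      reference: float) -> pd.DataFrame:
    """Percent difference of normalized profile maxima between sphere
    pairs: 100 x (max_large - max_small) / max_large.

    ``reference`` (e.g. the true sphere concentration) normalizes every
    profile first.  The (largest, smallest) pair is the headline number;
    all ordered pairs are returned.
    """
    if reference == 0:
        raise ValueError("zero normalization reference")
    diams = sorted(profiles, reverse=True)
    maxima = {d: profiles[d].max / reference for d in diams}
    rows = []
    for i, d_large in enumerate(diams):
        for d_small in diams[i + 1:]:
            m_l, m_s = maxima[d_large], maxima[d_small]
            rows.append({"diameter_large_mm": d_large, "diameter_small_mm": d_small,
                         "max_large": m_l, "max_small": m_s,
                         "difference_percent": 100.0 * (m_l - m_s) / m_l})
    return pd.DataFrame(rows)
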