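"""Count-to-activity calibration, recovery coefficients and contrast.

The calibration applies a scalar quantitative factor

    QF = 1 / (Cs x dt x V_voxel)

(camera sensitivity x total acquisition time x reconstructed voxel
volume) to convert image counts into activity concentration.  Recovery
coefficients compare the mean measured concentration in each sphere VOI
with the true filled concentration; contrast is the measured
sphere-to-background ratio normalized by the known true ratio A:

    C = (VOI_m / VOI_b) / A

which is unit-free, so counts and concentration images give identical
contrast.  Note this ratio-normalized form is not the NU2
percent-contrast (H/B - 1)/(ratio - 1); the latter is available behind
an explicit flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VoxelGrid, Volume
from .isotopes import decay_correct, get_isotope
from .phantom import PhantomFill, PhantomSpec, background_mask, sphere_masks
from .simulate import ReconSettings, ScanProtocol, simulate_scan


@dataclass(frozen=True)
class QuantitativeFactor:
    """QF = 1/(Cs x dt x V_voxel), with the components kept for audit.

    value is in Bq/mL per count when Cs is counts/s per Bq, dt in
    seconds and V_voxel in mL.
    """

    cs_cps_per_bq: float
    dt_s: float
    v_voxel_ml: float

    def __post_init__(self):
        if min(self.cs_cps_per_bq, self.dt_s, self.v_voxel_ml) <= 0:
            raise ValueError("Cs, dt and V_voxel must all be positive")

    @property
    def value(self) -> float:
        """Bq/mL per reconstructed count."""
        return 1.0 / (self.cs_cps_per_bq * self.dt_s * self.v_voxel_ml)


def quantitative_factor(cs_cps_per_bq: float, dt_s: float,
                        v_voxel_ml: float) -> QuantitativeFactor:
    return QuantitativeFactor(cs_cps_per_bq, dt_s, v_voxel_ml)


def qf_for(protocol: ScanProtocol, grid: VoxelGrid) -> QuantitativeFactor:
    """The quantitative factor implied by a protocol and image grid."""
    return QuantitativeFactor(protocol.sensitivity_cps_per_bq,
                              protocol.total_time_s, grid.voxel_volume_ml)


def counts_to_concentration(image: Volume, qf: QuantitativeFactor) -> Volume:
    """Voxelwise counts x QF, rendered in kBq/mL (QF itself is Bq/mL per
    count; the Bq -> kBq step is the explicit /1000 here)."""
    if image.unit != "counts":
        raise ValueError(f"expected a counts image, got unit {image.unit!r}")
    return image.with_values(image.values * (qf.value / 1000.0), unit="kBq/mL")


@dataclass(frozen=True)
class RecoveryResult:
    diameter_mm: float
    measured_kbq_ml: float
    true_kbq_ml: float

    @property
    def rc(self) -> float:
        """Recovery coefficient: measured / true mean concentration.  May
        exceed 1 under resolution modeling."""
        return self.measured_kbq_ml / self.true_kbq_ml


@dataclass(frozen=True)
class ContrastResult:
    diameter_mm: float
    voi_mean: float          # VOI_m, sphere mean (image units)
    background_mean: float   # VOI_b
    true_ratio: float        # A

    @property
    def contrast(self) -> float:
        """C = (VOI_m / VOI_b) / A; equals 1/A x measured ratio, so a
        sphere indistinguishable from background scores 1/A, and perfect
        recovery scores 1."""
        return (self.voi_mean / self.background_mean) / self.true_ratio

    @property
    def nu2_percent_contrast(self) -> float:
        """The NU2-style variant (H/B - 1)/(A - 1); not the default."""
        return (self.voi_mean / self.background_mean - 1.0) / (self.true_ratio - 1.0)


def recovery_coefficients(image: Volume, masks: list[np.ndarray],
                          spec: PhantomSpec,
                          decay_to_scan_h: float | None = None,
                          ) -> list[RecoveryResult]:
    """Per-sphere recovery coefficients, ordered by descending diameter.

    ``decay_to_scan_h`` optionally decay-corrects the assayed true
    concentration to the scan time; off by default.
    """
    if image.unit != "kBq/mL":
        raise ValueError(
            f"recovery needs a concentration image (kBq/mL), got {image.unit!r}; "
            "apply the quantitative factor first")
    true_conc = spec.fill.sphere_concentration
    if decay_to_scan_h is not None:
        true_conc = decay_correct(true_conc, get_isotope(spec.fill.isotope),
                                  decay_to_scan_h)
    out = []
    for sphere, mask in zip(spec.spheres, masks):
        out.append(RecoveryResult(sphere.diameter, image.mean_over(mask), true_conc))
    return sorted(out, key=lambda r: -r.diameter_mm)


def contrast(image: Volume, masks: list[np.ndarray], bg_mask: np.ndarray,
             spec: PhantomSpec) -> list[ContrastResult]:
    """Per-sphere ratio-normalized contrast from a warm-background image.

    Works on counts or concentration images alike (the ratio cancels any
    global scale).
    """
    fill: PhantomFill = spec.fill
    a = fill.true_ratio  # raises for cold background
    bg = image.mean_over(bg_mask)
    if bg == 0:
        raise ValueError("background VOI mean is zero; contrast undefined")
    out = [ContrastResult(s.diameter, image.mean_over(m), bg, a)
           for s, m in zip(spec.spheres, masks)]
    return sorted(out, key=lambda r: -r.diameter_mm)


def background_cv(image: Volume, bg_mask: np.ndarray) -> float:
    """Coefficient of variation over the background VOI — the noise
    metric that grows with OSEM iterations on noisy data."""
    vals = image.values[np.asarray(bg_mask, bool)]
    return float(vals.std() / vals.mean())


def iteration_sweep(spec: PhantomSpec, protocol: ScanProtocol, grid: VoxelGrid,
                    seed: int | None = 0,
                    iterations_list: tuple[int, ...] = (1, 2, 4, 8, 16, 32),
                    subsets: int = 4, post_filter_fwhm_mm: float = 8.40,
                    resolution_modeling: bool = False,
                    supersample: int = 4, return_study: bool = False):
    """Reconstruct one acquisition at several iteration counts and
    quantify each, on the same noise realization.

    Returns a tidy table with one row per (iterations, sphere) carrying
    RC, contrast (warm fills only) and the background noise CV; with
    ``return_study`` a (table, SimulatedStudy) pair, the study holding
    every checkpoint volume.
    """
    if not iterations_list:
        raise ValueError("iterations_list must be non-empty")
    settings = ReconSettings(iterations=max(iterations_list), subsets=subsets,
                             post_filter_fwhm_mm=post_filter_fwhm_mm,
                             resolution_modeling=resolution_modeling)
    study = simulate_scan(spec, protocol, settings, grid, seed=seed,
                          supersample=supersample,
                          checkpoints=sorted(set(iterations_list)))
    masks = sphere_masks(spec, grid)
    bg = background_mask(spec, grid)
    qf = qf_for(protocol, grid)
    rows = []
    for it, counts_vol in study.checkpoint_volumes.items():
        conc = counts_to_concentration(counts_vol, qf)
        rcs = recovery_coefficients(conc, masks, spec)
        cons = {c.diameter_mm: c for c in contrast(conc, masks, bg, spec)} \
            if not spec.fill.is_cold else {}
        cv = background_cv(conc, bg)
        for r in rcs:
            rows.append({
                "isotope": spec.fill.isotope, "modality": protocol.modality,
                "iterations": it, "subsets": subsets,
                "post_filter_fwhm_mm": post_filter_fwhm_mm,
                "resolution_modeling": resolution_modeling,
                "diameter_mm": r.diameter_mm,
                "measured_kbq_ml": r.measured_kbq_ml,
                "true_kbq_ml": r.true_kbq_ml,
                "rc": r.rc,
                "contrast": cons[r.diameter_mm].contrast if cons else np.nan,
                "background_cv": cv,
            })
    table = pd.DataFrame(rows)
    return (table, study) if return_study else table
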