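"""NEMA IEC body-phantom geometry: spheres, torso contour, fills,
rasterization into activity volumes and VOI masks.

The phantom carries six fillable spheres (37, 28, 22, 17, 13 and 10 mm
inner diameter) whose centres sit on a 114.4-mm-diameter circle in one
transaxial plane, inside a torso-shaped body compartment.  The body may
be filled warm (roughly one tenth of the sphere concentration) or cold
(non-radioactive water).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .core import VoxelGrid, Volume

#: inner diameters (mm) of the standard sphere set, largest first
STANDARD_SPHERE_DIAMETERS = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

#: diameter (mm) of the circle on which the sphere centres sit
SPHERE_RING_DIAMETER = 114.4


class GeometryWarning(UserWarning):
    """Raised (as a warning) for grids too coarse for the geometry."""


@dataclass(frozen=True)
class SphereSpec:
    """One fillable sphere: inner diameter and centre in the phantom frame."""

    diameter: float          # mm
    center: tuple[float, float, float]  # (z, y, x) mm

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("sphere diameter must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3


@dataclass(frozen=True)
class BodyContour:
    """Torso-shaped body compartment, extruded along the axial direction.

    mode "nema": the standard simplified torso cross-section — two
    half-circle shoulders of radius height/2 joined by a rectangle
    (overall 300 x 230 mm).  mode "elliptical": an elliptical cylinder
    with the same overall extents, for fast tests.  The exact interior
    dimensions do not enter any reported metric; both modes satisfy the
    mask-partition identity.
    """

    mode: str = "nema"           # "nema" | "elliptical"
    width: float = 300.0         # left-right extent, mm
    height: float = 230.0        # anterior-posterior extent, mm
    axial_extent: float = 180.0  # interior length, mm

    def __post_init__(self):
        if self.mode not in ("nema", "elliptical"):
            raise ValueError(f"unknown contour mode {self.mode!r}")
        if min(self.width, self.height, self.axial_extent) <= 0:
            raise ValueError("contour dimensions must be positive")
        if self.mode == "nema" and self.width < self.height:
            raise ValueError("nema contour requires width >= height")

    def contains(self, z, y, x) -> np.ndarray:
        """Vectorized point-membership test in the phantom frame."""
        z, y, x = np.broadcast_arrays(np.asarray(z, float), np.asarray(y, float),
                                      np.asarray(x, float))
        in_axial = np.abs(z) <= self.axial_extent / 2.0
        if self.mode == "elliptical":
            a, b = self.width / 2.0, self.height / 2.0
            in_plane = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        else:
            r = self.height / 2.0            # shoulder radius
            half_flat = self.width / 2.0 - r  # half-width of the rectangle
            dx = np.maximum(np.abs(x) - half_flat, 0.0)
            in_plane = dx ** 2 + y ** 2 <= r ** 2
        return in_axial & in_plane

    def interior_distance(self, z, y, x) -> np.ndarray:
        """Distance (mm) from a point to the contour boundary, positive
        inside; used to carve an edge margin off the background VOI."""
        z, y, x = np.broadcast_arrays(np.asarray(z, float), np.asarray(y, float),
                                      np.asarray(x, float))
        d_axial = self.axial_extent / 2.0 - np.abs(z)
        if self.mode == "elliptical":
            # approximate radial distance via the scaled radius
            a, b = self.width / 2.0, self.height / 2.0
            rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
            d_plane = (1.0 - rho) * min(a, b)
        else:
            r = self.height / 2.0
            half_flat = self.width / 2.0 - r
            dx = np.maximum(np.abs(x) - half_flat, 0.0)
            d_plane = r - np.sqrt(dx ** 2 + y ** 2)
        return np.minimum(d_axial, d_plane)


@dataclass(frozen=True)
class PhantomFill:
    """Activity concentrations loaded into the phantom.

    ``background_concentration`` of 0 denotes a cold (water) background;
    the true sphere-to-background ratio A is then undefined.
    """

    isotope: str
    sphere_concentration: float       # kBq/mL
    background_concentration: float   # kBq/mL; 0 = cold background

    def __post_init__(self):
        if self.sphere_concentration < 0 or self.background_concentration < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def is_cold(self) -> bool:
        return self.background_concentration == 0.0

    @property
    def true_ratio(self) -> float:
        """A = sphere / background concentration; computed, never assumed
        to equal the nominal 10."""
        if self.is_cold:
            raise ValueError("true ratio A is undefined for a cold background")
        return self.sphere_concentration / self.background_concentration


@dataclass(frozen=True)
class PhantomSpec:
    spheres: tuple[SphereSpec, ...]
    contour: BodyContour
    fill: PhantomFill

    def __post_init__(self):
        object.__setattr__(self, "spheres", tuple(self.spheres))
        self._validate()

    def _validate(self):
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1:]:
                gap = np.linalg.norm(np.subtract(a.center, b.center))
                if gap < a.radius + b.radius:
                    raise ValueError(
                        f"spheres of diameter {a.diameter} and {b.diameter} mm overlap")
        for s in self.spheres:
            zc, yc, xc = s.center
            # sample the sphere surface along the principal axes
            for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)]:
                p = (zc + dz * s.radius, yc + dy * s.radius, xc + dx * s.radius)
                if not self.contour.contains(*p):
                    raise ValueError(
                        f"sphere of diameter {s.diameter} mm extends outside the body contour")

    @property
    def diameters(self) -> tuple[float, ...]:
        return tuple(s.diameter for s in self.spheres)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "isotope": self.fill.isotope,
            "sphere_concentration_kbq_ml": self.fill.sphere_concentration,
            "background_concentration_kbq_ml": self.fill.background_concentration,
            "background_mode": "cold" if self.fill.is_cold else "warm",
            "contour": {"mode": self.contour.mode, "width_mm": self.contour.width,
                        "height_mm": self.contour.height,
                        "axial_extent_mm": self.contour.axial_extent},
            "spheres": [{"diameter_mm": s.diameter, "center_mm": list(s.center)}
                        for s in self.spheres],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        fill = PhantomFill(d["isotope"], d["sphere_concentration_kbq_ml"],
                           d["background_concentration_kbq_ml"])
        c = d.get("contour", {})
        contour = BodyContour(c.get("mode", "nema"), c.get("width_mm", 300.0),
                              c.get("height_mm", 230.0), c.get("axial_extent_mm", 180.0))
        spheres = tuple(SphereSpec(s["diameter_mm"], tuple(s["center_mm"]))
                        for s in d["spheres"])
        return cls(spheres, contour, fill)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(text))


def default_nema_spec(fill: PhantomFill,
                      contour: BodyContour | None = None) -> PhantomSpec:
    """The standard six-sphere NEMA IEC phantom for a given fill.

    Sphere centres are coplanar in the central transaxial plane (z = 0),
    equally spaced at 60 degrees on a 114.4-mm-diameter circle, largest
    sphere at angle 0 (the +x, left-right axis).
    """
    ring_r = SPHERE_RING_DIAMETER / 2.0
    spheres = []
    for k, diam in enumerate(STANDARD_SPHERE_DIAMETERS):
        ang = np.deg2rad(60.0 * k)
        spheres.append(SphereSpec(diam, (0.0, ring_r * np.sin(ang), ring_r * np.cos(ang))))
    return PhantomSpec(tuple(spheres), contour or BodyContour(), fill)


# -- rasterization ---------------------------------------------------------

def _sphere_bbox(sphere: SphereSpec, grid: VoxelGrid, pad: float = 0.0):
    lo = grid.world_to_index(np.subtract(sphere.center, sphere.radius + pad))
    hi = grid.world_to_index(np.add(sphere.center, sphere.radius + pad))
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int) + 1, grid.shape)
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def voxelize(spec: PhantomSpec, grid: VoxelGrid, supersample: int = 4) -> Volume:
    """Rasterize the filled phantom into an activity-concentration volume.

    Each voxel receives background + (sphere - background) x the fraction
    of ``supersample``^3 sub-voxel points falling inside the sphere;
    voxels whose centre lies outside the body contour are 0.  Increasing
    ``supersample`` converges the integrated sphere activity to the
    analytic (4/3) pi r^3 value.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if spec.spheres:
        smallest = min(s.diameter for s in spec.spheres)
        if smallest < 2 * min(grid.spacing):
            warnings.warn(
                f"grid spacing {min(grid.spacing)} mm puts fewer than 2 voxels across "
                f"the smallest ({smallest} mm) sphere", GeometryWarning)
    z, y, x = grid.coord_arrays()
    body = spec.contour.contains(z, y, x)
    values = np.where(body, spec.fill.background_concentration, 0.0)
    excess = spec.fill.sphere_concentration - spec.fill.background_concentration
    # sub-voxel offsets centred in the voxel
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    for sphere in spec.spheres:
        box = _sphere_bbox(sphere, grid)
        zz = grid.axis_coords(0)[box[0]]
        yy = grid.axis_coords(1)[box[1]]
        xx = grid.axis_coords(2)[box[2]]
        frac = np.zeros((zz.size, yy.size, xx.size))
        for oz in off:
            dz2 = (zz + oz * grid.spacing[0] - sphere.center[0])[:, None, None] ** 2
            for oy in off:
                dy2 = (yy + oy * grid.spacing[1] - sphere.center[1])[None, :, None] ** 2
                for ox in off:
                    dx2 = (xx + ox * grid.spacing[2] - sphere.center[2])[None, None, :] ** 2
                    frac += dz2 + dy2 + dx2 <= sphere.radius ** 2
        frac /= supersample ** 3
        values[box] += excess * frac * body[box]
    return Volume(grid, values, "kBq/mL")


def contour_mask(spec: PhantomSpec, grid: VoxelGrid) -> np.ndarray:
    """Binary mask of voxels whose centre lies inside the body contour."""
    z, y, x = grid.coord_arrays()
    return spec.contour.contains(z, y, x)


def sphere_masks(spec: PhantomSpec, grid: VoxelGrid,
                 margin: float = 0.0) -> list[np.ndarray]:
    """One binary VOI mask per sphere (voxel-centre-in-sphere rule).

    ``margin`` (mm) uniformly enlarges the radius, used to carve a guard
    band around the spheres out of the background VOI.
    """
    masks = []
    z, y, x = grid.coord_arrays()
    for sphere in spec.spheres:
        r = sphere.radius + margin
        m = ((z - sphere.center[0]) ** 2 + (y - sphere.center[1]) ** 2
             + (x - sphere.center[2]) ** 2) <= r ** 2
        if not m.any():
            warnings.warn(f"sphere of diameter {sphere.diameter} mm intersects no "
                          "voxel centre on this grid", GeometryWarning)
        masks.append(m)
    return masks


def background_mask(spec: PhantomSpec, grid: VoxelGrid,
                    sphere_margin: float = 0.0,
                    edge_margin: float = 0.0) -> np.ndarray:
    """Background VOI: the full body contour minus the sphere VOIs.

    With the default zero margins this is exactly the contour mask minus
    the sphere masks, so contour = background + spheres voxel-by-voxel.
    Positive ``sphere_margin`` additionally excludes a shell around each
    sphere, and ``edge_margin`` a rim inside the contour boundary.
    """
    if sphere_margin < 0 or edge_margin < 0:
        raise ValueError("margins must be non-negative")
    mask = contour_mask(spec, grid)
    if edge_margin > 0:
        z, y, x = grid.coord_arrays()
        mask = mask & (spec.contour.interior_distance(z, y, x) >= edge_margin)
    for m in sphere_masks(spec, grid, margin=sphere_margin):
        mask = mask & ~m
    if not mask.any():
        raise ValueError("background mask is empty; reduce the margins")
    return mask


def attenuation_map(spec: PhantomSpec, grid: VoxelGrid, mu: float) -> Volume:
    """Uniform water-equivalent attenuation map (1/mm) from the geometry."""
    return Volume(grid, contour_mask(spec, grid) * float(mu), "1/mm")
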