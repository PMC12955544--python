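"""Voxel grids and unit-carrying volumes.

Index order is (axial, anterior-posterior, left-right), abbreviated
(z, y, x).  All lengths are millimetres; activity concentrations are
kBq/mL; reconstructed raw images carry the unit ``counts``.

The phantom frame places the origin at the centre of the sphere plane,
and by default a grid is positioned so that its geometric centre
coincides with that origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: units a Volume may declare
VALID_UNITS = ("kBq/mL", "counts", "dimensionless", "1/mm")


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D grid with physical spacing.

    Parameters
    ----------
    shape
        Number of voxels along (z, y, x).
    spacing
        Voxel size in mm along (z, y, x); all entries positive.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).  When
        omitted, the grid is centred on the phantom-frame origin.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths (mm), got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if self.origin is None:
            origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        else:
            origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "origin", origin)

    # -- geometry ---------------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mL = 1000 mm^3); the V_voxel of the
        count-to-activity calibration factor."""
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def coord_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (z, y, x) world-coordinate arrays of voxel centres."""
        z = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        x = self.axis_coords(2)[None, None, :]
        return z, y, x

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm, shape (..., 3) in z,y,x order) to
        fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def describe(self) -> dict:
        return {"shape": list(self.shape), "spacing_mm": list(self.spacing),
                "origin_mm": list(self.origin)}


@dataclass
class Volume:
    """A scalar field on a :class:`VoxelGrid` with a declared unit.

    The unit is propagated (and checked) through every operation in the
    package so that counts are never silently treated as activity.
    """

    grid: VoxelGrid
    values: np.ndarray
    unit: str = "kBq/mL"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Volume":
        return Volume(self.grid, values, unit if unit is not None else self.unit)

    def total_activity_bq(self) -> float:
        """Integral of the field in Bq; only meaningful for kBq/mL volumes."""
        if self.unit != "kBq/mL":
            raise ValueError(f"total activity undefined for unit {self.unit!r}")
        return float(self.values.sum() * 1000.0 * self.grid.voxel_volume_ml)

    def mean_over(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        return float(self.values[mask].mean())


# -- NIfTI I/O -------------------------------------------------------------
#
# Volumes are stored (z, y, x); NIfTI wants the fastest-varying axis first,
# so arrays are transposed to (x, y, z) on write and back on read.  The
# value unit travels in a JSON sidecar next to the image.

def write_nifti(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    data = np.ascontiguousarray(vol.values.transpose(2, 1, 0))
    affine = np.diag([vol.grid.spacing[2], vol.grid.spacing[1], vol.grid.spacing[0], 1.0])
    affine[:3, 3] = [vol.grid.origin[2], vol.grid.origin[1], vol.grid.origin[0]]
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps({"unit": vol.unit, "grid": vol.grid.describe()}, indent=1))
    return path


def read_nifti(path: str | Path, unit: str | None = None) -> Volume:
    """Load a NIfTI volume; the unit comes from the sidecar unless given."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3][::-1])
    origin = tuple(float(o) for o in img.affine[:3, 3][::-1])
    grid = VoxelGrid(data.shape, spacing, origin)
    if unit is None:
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
        if sidecar.exists():
            unit = json.loads(sidecar.read_text()).get("unit", "dimensionless")
        else:
            unit = "dimensionless"
    return Volume(grid, data, unit)
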