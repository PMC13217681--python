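"""Binary voxel masks on a regular anisotropic grid.

A :class:`VoxelMask` is the in-memory representation of a delineated
structure (an observer's pre- or post-training contour, or the expert
reference volume): a 3-D boolean occupancy array together with the physical
voxel spacing in millimetres and the physical coordinate of the centre of
voxel ``(0, 0, 0)``.

Axis convention: axis 0 is the slice (superior-inferior) axis, axes 1 and 2
are in-plane.  All physical quantities are in millimetres; volumes are
reported in cm3.

NIfTI I/O maps the file's ``(i, j, k)`` axes to in-memory axes ``(2, 1, 0)``
so that the slowest-varying in-memory axis is the slice axis.  Only
axis-aligned affines (diagonal 3x3 part with positive scales) are accepted;
masks requiring resampling or reorientation are rejected with a clear error
rather than silently transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import InvalidGeometryError

__all__ = ["VoxelMask", "load_mask", "save_mask"]


@dataclass(frozen=True, eq=False)
class VoxelMask:
    """A binary structure mask on a regular grid.

    Parameters
    ----------
    occupancy
        3-D boolean array; ``True`` marks foreground voxels.
    spacing
        Physical voxel size per axis in mm, all strictly positive.
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise InvalidGeometryError(
                f"occupancy must be 3-D, got {occ.ndim}-D"
            )
        occ = occ.astype(bool, copy=False)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InvalidGeometryError(
                f"spacing must be three strictly positive values, got {self.spacing}"
            )
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise InvalidGeometryError(f"origin must have 3 components, got {self.origin}")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- basic queries -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    def is_empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VoxelMask") -> bool:
        """True if shapes and spacings (and origins) match exactly."""
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def require_same_grid(self, other: "VoxelMask") -> None:
        if not self.same_grid(other):
            raise InvalidGeometryError(
                "masks are on different grids: "
                f"shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}; resampling is not performed"
            )

    def foreground_coordinates(self) -> np.ndarray:
        """Physical coordinates (mm) of foreground voxel centres, shape (n, 3)."""
        idx = np.argwhere(self.occupancy)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def with_occupancy(self, occupancy: np.ndarray) -> "VoxelMask":
        """A new mask on the same grid with different occupancy."""
        return VoxelMask(occupancy, self.spacing, self.origin)


def _check_axis_aligned(affine: np.ndarray, atol: float = 1e-4) -> None:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > atol:
        raise InvalidGeometryError(
            "NIfTI affine contains rotation or shear; only axis-aligned "
            "scaling is supported (reorient/resample the mask externally)"
        )
    if np.any(np.diag(rot) <= 0):
        raise InvalidGeometryError(
            "NIfTI affine has non-positive scales (axis flips are not supported)"
        )


def load_mask(path: str | Path) -> VoxelMask:
    """Read a binary mask from a NIfTI file.

    Any nonzero voxel is foreground.  Spacing and origin are taken from the
    affine, which must be axis-aligned with positive scales.
    """
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    _check_axis_aligned(affine)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidGeometryError(
            f"{path}: expected a 3-D mask volume, got {data.ndim}-D"
        )
    occupancy = (data != 0).T  # file (i, j, k) -> memory (k, j, i): axis 0 = slice
    scales = np.diag(affine[:3, :3])
    spacing = (float(scales[2]), float(scales[1]), float(scales[0]))
    translation = affine[:3, 3]
    origin = (float(translation[2]), float(translation[1]), float(translation[0]))
    return VoxelMask(occupancy, spacing, origin)


def save_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as an uint8 NIfTI volume with an axis-aligned affine."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = (
        mask.spacing[2],
        mask.spacing[1],
        mask.spacing[0],
    )
    affine[:3, 3] = (mask.origin[2], mask.origin[1], mask.origin[0])
    data = mask.occupancy.T.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))
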