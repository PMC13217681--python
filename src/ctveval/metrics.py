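"""Spatial-overlap and boundary-accuracy metrics for contour pairs.

The evaluation battery compares a test mask (an observer's delineation)
against an expert reference on the same voxel grid:

* spatial overlap / consistency — Dice similarity coefficient (DSC),
  conformity index (CI, the Jaccard index), inclusion index (fraction of
  the reference covered by the test contour), relative volume difference
  (RVD, signed);
* geometric boundary accuracy — average surface distance (ASD), distance
  between centres of mass (DC), 95th-percentile Hausdorff distance (95%HD);
* absolute structure volume in cm3.

Conventions
-----------
The surface of a mask is the set of foreground voxels with at least one
background 6-neighbour (out-of-bounds counts as background); distances are
Euclidean between voxel centres, honouring anisotropic spacing.  ASD is
symmetric: the mean of the pooled bidirectional nearest-surface distance
list.  The percentile Hausdorff distance is the maximum of the two directed
p-th percentiles, using linear-interpolation percentiles; ``p=100`` recovers
the classical Hausdorff distance.  CI and DSC are tied by the identity
``ci = dsc / (2 - dsc)``.

Empty masks raise :class:`~ctveval.exceptions.UndefinedMetricError` rather
than returning a sentinel: a silent 0 would corrupt cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .exceptions import InvalidParameterError, UndefinedMetricError
from .mask import VoxelMask

__all__ = [
    "MetricSet",
    "METRIC_NAMES",
    "mask_volume",
    "dice",
    "conformity_index",
    "inclusion_index",
    "relative_volume_difference",
    "surface_mask",
    "surface_points",
    "directed_surface_distances",
    "average_surface_distance",
    "hausdorff_percentile",
    "centroid_distance",
    "metric_set",
]

#: Canonical metric names, in reporting order.
METRIC_NAMES = ("dsc", "ci", "inclusion", "rvd", "asd", "dc", "hd95", "volume")

# 6-connectivity structuring element for surface extraction.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class MetricSet:
    """The eight per-contour-pair quality numbers.

    ``dsc``, ``ci`` and ``inclusion`` are unitless in [0, 1]; ``rvd`` is a
    signed fraction (negative when the test contour is smaller than the
    reference); ``asd``, ``dc`` and ``hd95`` are in mm; ``volume`` is the
    test contour's volume in cm3.
    """

    dsc: float
    ci: float
    inclusion: float
    rvd: float
    asd: float
    dc: float
    hd95: float
    volume: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _require_non_empty(mask: VoxelMask, metric: str) -> None:
    if mask.is_empty():
        raise UndefinedMetricError(f"{metric} is undefined for an empty mask")


def mask_volume(mask: VoxelMask) -> float:
    """Volume of the foreground in cm3 (0 for an empty mask)."""
    return mask.n_foreground * mask.voxel_volume_mm3 / 1000.0


def _overlap_counts(a: VoxelMask, b: VoxelMask) -> tuple[int, int, int]:
    a.require_same_grid(b)
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    return inter, a.n_foreground, b.n_foreground


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); symmetric."""
    inter, na, nb = _overlap_counts(a, b)
    if na + nb == 0:
        raise UndefinedMetricError("dice is undefined when both masks are empty")
    return 2.0 * inter / (na + nb)


def conformity_index(a: VoxelMask, b: VoxelMask) -> float:
    """Conformity index |A∩B| / |A∪B| (the Jaccard index); symmetric."""
    inter, na, nb = _overlap_counts(a, b)
    union = na + nb - inter
    if union == 0:
        raise UndefinedMetricError(
            "conformity_index is undefined when both masks are empty"
        )
    return inter / union


def inclusion_index(test: VoxelMask, ref: VoxelMask) -> float:
    """Fraction of the reference volume covered by the test contour."""
    inter, _, nref = _overlap_counts(test, ref)
    if nref == 0:
        raise UndefinedMetricError(
            "inclusion_index is undefined for an empty reference"
        )
    return inter / nref


def relative_volume_difference(test: VoxelMask, ref: VoxelMask) -> float:
    """Signed relative volume difference (V_test - V_ref) / V_ref.

    Negative values mean the test contour is smaller than the reference.
    """
    test.require_same_grid(ref)
    if ref.is_empty():
        raise UndefinedMetricError(
            "relative_volume_difference is undefined for an empty reference"
        )
    return (test.n_foreground - ref.n_foreground) / ref.n_foreground


def surface_mask(mask: VoxelMask) -> np.ndarray:
    """Boolean array marking surface voxels.

    A surface voxel is a foreground voxel with at least one background
    6-neighbour; voxels on the array boundary count as surface.
    """
    _require_non_empty(mask, "surface")
    interior = ndimage.binary_erosion(
        mask.occupancy, structure=_STRUCT_6, border_value=0
    )
    return mask.occupancy & ~interior


def surface_points(mask: VoxelMask) -> np.ndarray:
    """Physical coordinates (mm) of surface voxel centres, shape (n, 3)."""
    surf = surface_mask(mask)
    return np.argwhere(surf) * np.asarray(mask.spacing) + np.asarray(mask.origin)


def directed_surface_distances(src: VoxelMask, dst: VoxelMask) -> np.ndarray:
    """For each surface voxel of ``src``, the Euclidean distance (mm) to the
    nearest surface voxel of ``dst``.

    Uses an exact Euclidean distance transform of the destination surface
    with anisotropic sampling, evaluated at the source surface voxels.
    """
    src.require_same_grid(dst)
    src_surf = surface_mask(src)
    dst_surf = surface_mask(dst)
    dt = ndimage.distance_transform_edt(~dst_surf, sampling=src.spacing)
    return dt[src_surf]


def average_surface_distance(a: VoxelMask, b: VoxelMask) -> float:
    """Symmetric average surface distance in mm.

    Mean of the pooled list concatenating the directed nearest-surface
    distances a→b and b→a (not the mean of the two directed means); zero
    iff the two surfaces coincide.
    """
    d_ab = directed_surface_distances(a, b)
    d_ba = directed_surface_distances(b, a)
    return float(np.concatenate([d_ab, d_ba]).mean())


def hausdorff_percentile(a: VoxelMask, b: VoxelMask, p: float = 95.0) -> float:
    """p-th percentile Hausdorff distance in mm.

    The maximum of the p-th percentiles (linear interpolation) of the two
    directed surface-distance lists; ``p=100`` is the classical Hausdorff
    distance.
    """
    if not 0.0 < p <= 100.0:
        raise InvalidParameterError(f"percentile must be in (0, 100], got {p}")
    d_ab = directed_surface_distances(a, b)
    d_ba = directed_surface_distances(b, a)
    return float(max(np.percentile(d_ab, p), np.percentile(d_ba, p)))


def centroid_distance(a: VoxelMask, b: VoxelMask) -> float:
    """Euclidean distance (mm) between the physical-space centres of mass.

    The centroid is the unweighted mean of foreground voxel centres.
    """
    a.require_same_grid(b)
    _require_non_empty(a, "centroid_distance")
    _require_non_empty(b, "centroid_distance")
    ca = a.foreground_coordinates().mean(axis=0)
    cb = b.foreground_coordinates().mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def metric_set(test: VoxelMask, ref: VoxelMask, hd_percentile: float = 95.0) -> MetricSet:
    """All eight quality metrics of ``test`` against ``ref`` in one pass.

    The two distance transforms are shared across ASD and the percentile
    Hausdorff distance, so this is cheaper than calling each metric
    separately; the values are identical.
    """
    test.require_same_grid(ref)
    _require_non_empty(ref, "metric_set (reference)")
    _require_non_empty(test, "metric_set (test mask)")
    if not 0.0 < hd_percentile <= 100.0:
        raise InvalidParameterError(
            f"percentile must be in (0, 100], got {hd_percentile}"
        )

    d_tr = directed_surface_distances(test, ref)
    d_rt = directed_surface_distances(ref, test)
    pooled = np.concatenate([d_tr, d_rt])
    return MetricSet(
        dsc=dice(test, ref),
        ci=conformity_index(test, ref),
        inclusion=inclusion_index(test, ref),
        rvd=relative_volume_difference(test, ref),
        asd=float(pooled.mean()),
        dc=centroid_distance(test, ref),
        hd95=float(
            max(np.percentile(d_tr, hd_percentile), np.percentile(d_rt, hd_percentile))
        ),
        volume=mask_volume(test),
    )
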