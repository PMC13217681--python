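"""Shared fixtures and brute-force oracles for the test suite.

The oracle functions recompute surface extraction and surface distances
by exhaustive enumeration, independently of the package's distance-
transform implementation, so they stay valid whatever the implementation
does internally.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ctveval.mask import VoxelMask


def make_cube(
    shape=(20, 20, 20),
    lo=(5, 5, 5),
    size=(10, 10, 10),
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> VoxelMask:
    occ = np.zeros(shape, dtype=bool)
    sl = tuple(slice(a, a + s) for a, s in zip(lo, size))
    occ[sl] = True
    return VoxelMask(occ, spacing, origin)


def random_mask(
    rng: np.random.Generator,
    shape=(12, 12, 12),
    spacing=(1.0, 1.0, 1.0),
    p=0.3,
) -> VoxelMask:
    """A random non-empty blob: thresholded smooth noise."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    occ = field > np.quantile(field, 1 - p)
    if not occ.any():  # pragma: no cover - quantile guarantees foreground
        occ[tuple(d // 2 for d in shape)] = True
    return VoxelMask(occ, spacing)


def oracle_surface_indices(occ: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with a background 6-neighbour, by exhaustive check."""
    out = []
    shape = occ.shape
    for idx in np.argwhere(occ):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            outside = not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2])
            if outside or not occ[ni, nj, nk]:
                out.append((int(i), int(j), int(k)))
                break
    return out


def oracle_surface_points(mask: VoxelMask) -> np.ndarray:
    idx = np.asarray(oracle_surface_indices(mask.occupancy), dtype=float)
    return idx * np.asarray(mask.spacing) + np.asarray(mask.origin)


def oracle_directed_distances(src: VoxelMask, dst: VoxelMask) -> np.ndarray:
    """All-pairs minimum distances from src surface to dst surface."""
    ps = oracle_surface_points(src)
    pd_ = oracle_surface_points(dst)
    return cdist(ps, pd_).min(axis=1)


def oracle_centroid_distance(a: VoxelMask, b: VoxelMask) -> float:
    ca = a.foreground_coordinates().mean(axis=0)
    cb = b.foreground_coordinates().mean(axis=0)
    return float(np.sqrt(((ca - cb) ** 2).sum()))


def exact_wilcoxon_two_sided_p(diffs: np.ndarray) -> float:
    """Exact two-sided sign-flip p-value for the signed-rank statistic.

    Enumerates all 2^n sign assignments of the absolute-difference ranks
    (valid for tie-free nonzero differences) and doubles the smaller tail
    of the null distribution of the positive-rank sum.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_plus = ranks[diffs > 0].sum()
    total = 0
    le = 0
    ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        le += w <= w_plus
        ge += w >= w_plus
    return min(1.0, 2.0 * min(le, ge) / total)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
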