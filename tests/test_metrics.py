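"""Overlap and surface-distance metrics: worked examples, brute-force
oracle agreement, and the algebraic/geometric invariants of the battery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctveval.exceptions import InvalidParameterError, UndefinedMetricError
from ctveval.mask import VoxelMask
from ctveval.metrics import (
    average_surface_distance,
    centroid_distance,
    conformity_index,
    dice,
    directed_surface_distances,
    hausdorff_percentile,
    inclusion_index,
    mask_volume,
    metric_set,
    relative_volume_difference,
    surface_points,
)

from conftest import (
    make_cube,
    oracle_centroid_distance,
    oracle_directed_distances,
    oracle_surface_indices,
    random_mask,
)


def shifted_cube_pair():
    """10^3 cube vs the same cube shifted 5 voxels along axis 0, 1 mm iso."""
    a = make_cube(shape=(25, 20, 20), lo=(5, 5, 5), size=(10, 10, 10))
    b = make_cube(shape=(25, 20, 20), lo=(10, 5, 5), size=(10, 10, 10))
    return a, b


def single_voxel(shape, idx, spacing=(1.0, 1.0, 1.0)):
    occ = np.zeros(shape, dtype=bool)
    occ[idx] = True
    return VoxelMask(occ, spacing)


class TestVolume:
    @pytest.mark.parametrize(
        "n_voxels, spacing, expected",
        [(1000, (1, 1, 1), 1.0), (100, (1, 2, 5), 1.0), (0, (1, 1, 1), 0.0)],
    )
    def test_unit_conversion(self, n_voxels, spacing, expected):
        occ = np.zeros((10, 10, 20), dtype=bool)
        occ.flat[:n_voxels] = True
        assert mask_volume(VoxelMask(occ, spacing)) == pytest.approx(expected)


class TestOverlapMetrics:
    def test_identical_masks(self):
        a = make_cube()
        assert dice(a, a) == 1.0
        assert conformity_index(a, a) == 1.0
        assert inclusion_index(a, a) == 1.0
        assert relative_volume_difference(a, a) == 0.0

    def test_disjoint_masks(self):
        a = make_cube(shape=(20, 20, 20), lo=(0, 0, 0), size=(5, 5, 5))
        b = make_cube(shape=(20, 20, 20), lo=(10, 10, 10), size=(5, 5, 5))
        assert dice(a, b) == 0.0
        assert inclusion_index(a, b) == 0.0

    def test_shifted_cube_counts(self):
        a, b = shifted_cube_pair()
        assert dice(a, b) == pytest.approx(0.5)
        assert conformity_index(a, b) == pytest.approx(1 / 3)
        assert inclusion_index(a, b) == pytest.approx(0.5)
        assert relative_volume_difference(a, b) == 0.0

    @pytest.mark.parametrize("factor, expected", [(2.0, 1.0), (0.5, -0.5)])
    def test_rvd_sign_convention(self, factor, expected):
        ref = make_cube(shape=(20, 20, 20), lo=(2, 2, 2), size=(8, 10, 10))
        n_test = int(ref.n_foreground * factor)
        occ = np.zeros_like(ref.occupancy)
        occ.flat[:n_test] = True
        test = VoxelMask(occ, ref.spacing)
        assert relative_volume_difference(test, ref) == pytest.approx(expected)

    def test_superset_inclusion_is_one(self):
        ref = make_cube(shape=(20, 20, 20), lo=(6, 6, 6), size=(6, 6, 6))
        test = make_cube(shape=(20, 20, 20), lo=(4, 4, 4), size=(10, 10, 10))
        assert inclusion_index(test, ref) == 1.0

    def test_empty_masks_raise(self):
        empty = VoxelMask(np.zeros((5, 5, 5), dtype=bool), (1, 1, 1))
        full = make_cube(shape=(5, 5, 5), lo=(1, 1, 1), size=(2, 2, 2))
        with pytest.raises(UndefinedMetricError):
            dice(empty, empty)
        with pytest.raises(UndefinedMetricError):
            conformity_index(empty, empty)
        with pytest.raises(UndefinedMetricError):
            inclusion_index(full, empty)
        with pytest.raises(UndefinedMetricError):
            relative_volume_difference(full, empty)


class TestSurfaceExtraction:
    def test_single_voxel_surface(self):
        mask = single_voxel((5, 5, 5), (2, 2, 2), spacing=(2.0, 3.0, 1.0))
        np.testing.assert_allclose(surface_points(mask), [[4.0, 6.0, 2.0]])

    @pytest.mark.parametrize("size, expected", [(3, 26), (5, 98)])
    def test_solid_cube_surface_count(self, size, expected):
        # 98 for the 5-cube was frozen from the exhaustive neighbour check
        mask = make_cube(
            shape=(size + 4,) * 3, lo=(2, 2, 2), size=(size,) * 3
        )
        pts = surface_points(mask)
        assert len(pts) == expected
        assert len(oracle_surface_indices(mask.occupancy)) == expected

    def test_array_boundary_counts_as_surface(self):
        mask = VoxelMask(np.ones((3, 3, 3), dtype=bool), (1, 1, 1))
        assert len(surface_points(mask)) == 26  # all but the centre voxel

    def test_empty_mask_raises(self):
        with pytest.raises(UndefinedMetricError):
            surface_points(VoxelMask(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)))


class TestSurfaceDistances:
    def test_identical_masks_all_zero(self):
        a = make_cube()
        assert np.all(directed_surface_distances(a, a) == 0.0)
        assert average_surface_distance(a, a) == 0.0
        assert hausdorff_percentile(a, a, 95) == 0.0

    def test_single_voxel_pair_3mm(self):
        a = single_voxel((9, 5, 5), (1, 2, 2))
        b = single_voxel((9, 5, 5), (4, 2, 2))
        np.testing.assert_allclose(directed_surface_distances(a, b), [3.0])
        assert average_surface_distance(a, b) == pytest.approx(3.0)
        assert hausdorff_percentile(a, b, 95) == pytest.approx(3.0)

    def test_percentile_out_of_range_rejected(self):
        a = make_cube()
        with pytest.raises(InvalidParameterError):
            hausdorff_percentile(a, a, 0)
        with pytest.raises(InvalidParameterError):
            hausdorff_percentile(a, a, 101)

    @pytest.mark.parametrize("seed", range(5))
    def test_directed_distances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_mask(rng, shape=(12, 12, 12), spacing=(2.0, 1.0, 1.5))
        b = random_mask(rng, shape=(12, 12, 12), spacing=(2.0, 1.0, 1.5))
        got = np.sort(directed_surface_distances(a, b))
        want = np.sort(oracle_directed_distances(a, b))
        np.testing.assert_allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_asd_is_pooled_mean_of_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_mask(rng, shape=(10, 12, 11), spacing=(1.0, 1.25, 2.0))
        b = random_mask(rng, shape=(10, 12, 11), spacing=(1.0, 1.25, 2.0))
        pooled = np.concatenate(
            [oracle_directed_distances(a, b), oracle_directed_distances(b, a)]
        )
        assert average_surface_distance(a, b) == pytest.approx(
            pooled.mean(), abs=1e-9
        )

    def test_p100_recovers_classical_hausdorff(self, rng):
        a = random_mask(rng, shape=(11, 11, 11))
        b = random_mask(rng, shape=(11, 11, 11))
        want = max(
            oracle_directed_distances(a, b).max(),
            oracle_directed_distances(b, a).max(),
        )
        assert hausdorff_percentile(a, b, 100) == pytest.approx(want, abs=1e-9)


class TestCentroidDistance:
    def test_three_four_five_triangle(self):
        base = make_cube(shape=(30, 30, 30), lo=(5, 5, 5), size=(6, 6, 6))
        moved = make_cube(shape=(30, 30, 30), lo=(8, 9, 5), size=(6, 6, 6))
        # 3 voxels at 1 mm and 4 voxels at 1 mm: a 3-4-5 triangle
        assert centroid_distance(base, moved) == pytest.approx(5.0)

    def test_matches_direct_mean_computation(self, rng):
        a = random_mask(rng, shape=(12, 12, 12), spacing=(1.5, 2.0, 1.0))
        b = random_mask(rng, shape=(12, 12, 12), spacing=(1.5, 2.0, 1.0))
        assert centroid_distance(a, b) == pytest.approx(
            oracle_centroid_distance(a, b), abs=1e-9
        )


class TestMetricSet:
    def test_identity_pair(self):
        a = make_cube()
        ms = metric_set(a, a)
        assert (ms.dsc, ms.ci, ms.inclusion) == (1.0, 1.0, 1.0)
        assert (ms.rvd, ms.asd, ms.dc, ms.hd95) == (0.0, 0.0, 0.0, 0.0)

    def test_shifted_cube_values(self):
        a, b = shifted_cube_pair()
        ms = metric_set(a, b)
        assert ms.dsc == pytest.approx(0.5)
        assert ms.ci == pytest.approx(1 / 3)
        assert ms.inclusion == pytest.approx(0.5)
        assert ms.rvd == 0.0

    def test_fields_equal_standalone_operations(self, rng):
        test = random_mask(rng, shape=(13, 12, 11), spacing=(2.5, 1.0, 1.0))
        ref = random_mask(rng, shape=(13, 12, 11), spacing=(2.5, 1.0, 1.0))
        ms = metric_set(test, ref)
        assert ms.dsc == dice(test, ref)
        assert ms.ci == conformity_index(test, ref)
        assert ms.inclusion == inclusion_index(test, ref)
        assert ms.rvd == relative_volume_difference(test, ref)
        assert ms.asd == pytest.approx(average_surface_distance(test, ref), abs=1e-12)
        assert ms.dc == centroid_distance(test, ref)
        assert ms.hd95 == pytest.approx(hausdorff_percentile(test, ref, 95), abs=1e-12)
        assert ms.volume == mask_volume(test)

    def test_empty_test_mask_raises_with_context(self):
        ref = make_cube()
        empty = ref.with_occupancy(np.zeros_like(ref.occupancy))
        with pytest.raises(UndefinedMetricError, match="test mask"):
            metric_set(empty, ref)


class TestInvariants:
    """Symmetry, algebraic identities, and grid-transformation behaviour."""

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_dice_jaccard_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = random_mask(rng, shape=(10, 10, 10))
        b = random_mask(rng, shape=(10, 10, 10))
        assert dice(a, b) == dice(b, a)
        assert conformity_index(a, b) == conformity_index(b, a)
        assert average_surface_distance(a, b) == pytest.approx(
            average_surface_distance(b, a), abs=1e-12
        )
        assert hausdorff_percentile(a, b, 95) == hausdorff_percentile(b, a, 95)
        assert centroid_distance(a, b) == pytest.approx(
            centroid_distance(b, a), abs=1e-12
        )
        d, c = dice(a, b), conformity_index(a, b)
        assert c == pytest.approx(d / (2 - d), abs=1e-9)

    @given(seed=st.integers(0, 2**31 - 1), shift=st.tuples(*[st.integers(0, 3)] * 3))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_translation_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        a = random_mask(rng, shape=(10, 10, 10), spacing=(2.0, 1.0, 1.0))
        b = random_mask(rng, shape=(10, 10, 10), spacing=(2.0, 1.0, 1.0))

        def translate(m):
            occ = np.zeros((14, 14, 14), dtype=bool)
            occ[
                shift[0] : shift[0] + 10,
                shift[1] : shift[1] + 10,
                shift[2] : shift[2] + 10,
            ] = m.occupancy
            return VoxelMask(occ, m.spacing)

        pad = ((0, 4), (0, 4), (0, 4))
        a0 = VoxelMask(np.pad(a.occupancy, pad), a.spacing)
        b0 = VoxelMask(np.pad(b.occupancy, pad), b.spacing)
        at, bt = translate(a), translate(b)
        ms0 = metric_set(a0, b0)
        mst = metric_set(at, bt)
        for name in ("dsc", "ci", "inclusion", "rvd", "asd", "dc", "hd95", "volume"):
            assert getattr(mst, name) == pytest.approx(
                getattr(ms0, name), abs=1e-9
            ), name

    @given(seed=st.integers(0, 2**31 - 1), k=st.sampled_from([0.5, 2.0, 3.5]))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_spacing_linearity(self, seed, k):
        rng = np.random.default_rng(seed)
        a = random_mask(rng, shape=(10, 10, 10), spacing=(2.0, 1.0, 1.25))
        b = random_mask(rng, shape=(10, 10, 10), spacing=(2.0, 1.0, 1.25))
        scaled = tuple(k * s for s in a.spacing)
        ak = VoxelMask(a.occupancy, scaled)
        bk = VoxelMask(b.occupancy, scaled)
        ms1, msk = metric_set(a, b), metric_set(ak, bk)
        for name in ("dsc", "ci", "inclusion", "rvd"):
            assert getattr(msk, name) == getattr(ms1, name), name
        for name in ("asd", "dc", "hd95"):
            assert getattr(msk, name) == pytest.approx(
                k * getattr(ms1, name), rel=1e-9
            ), name
        assert msk.volume == pytest.approx(k**3 * ms1.volume, rel=1e-9)

    @given(seed=st.integers(0, 2**31 - 1), rounds=st.integers(1, 3))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_dilating_test_mask_never_decreases_inclusion(self, seed, rounds):
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        ref = random_mask(rng, shape=(10, 10, 10))
        test = random_mask(rng, shape=(10, 10, 10))
        prev = inclusion_index(test, ref)
        occ = test.occupancy
        for _ in range(rounds):
            occ = ndimage.binary_dilation(occ)
            cur = inclusion_index(test.with_occupancy(occ), ref)
            assert cur >= prev
            prev = cur
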