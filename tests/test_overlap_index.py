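import numpy as np
import pytest

from tauoi.overlap_index import (OiParams, binarize, compute_oi_pair,
                                 compute_overlap, filter_small_clusters,
                                 label_components)
from tauoi.volumes_io import BinaryMask

from _oracles import flood_fill_components, partition_from_labels
from conftest import full_roi, make_mask, make_volume


def block_mask(shape, lo, size):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:lo[0] + size[0], lo[1]:lo[1] + size[1], lo[2]:lo[2] + size[2]] = True
    return make_mask(m)


class TestBinarize:
    def test_strictly_above_threshold_is_set(self):
        vol = make_volume(np.full((3, 3, 3), 1.0))
        vol.data[1, 1, 1] = 1.41
        vol.data[0, 0, 0] = 1.40
        m = binarize(vol, full_roi((3, 3, 3)), 1.4)
        assert m.data[1, 1, 1] and not m.data[0, 0, 0]
        assert m.n_set == 1

    def test_outside_roi_never_set(self):
        vol = make_volume(np.full((3, 3, 3), 2.0))
        roi = make_mask(np.zeros((3, 3, 3), bool))
        roi.data[0, 0, 0] = True
        assert binarize(vol, roi, 1.4).n_set == 1

    def test_nonfinite_voxels_never_set(self):
        vol = make_volume(np.full((3, 3, 3), 2.0))
        vol.data[2, 2, 2] = np.nan
        vol.data[0, 1, 2] = np.inf   # +inf is non-finite, excluded
        m = binarize(vol, full_roi((3, 3, 3)), 1.4)
        assert not m.data[2, 2, 2] and not m.data[0, 1, 2]

    def test_non_strict_option_includes_boundary(self):
        vol = make_volume(np.full((2, 2, 2), 1.4))
        assert binarize(vol, full_roi((2, 2, 2)), 1.4, strict=False).n_set == 8


class TestLabelComponents:
    def _two_voxel_components(self, a, b, connectivity):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[a] = m[b] = True
        return label_components(make_mask(m), connectivity).n_clusters

    def test_face_neighbors_connect_everywhere(self):
        for conn in (6, 18, 26):
            assert self._two_voxel_components((0, 0, 0), (0, 0, 1), conn) == 1

    def test_edge_neighbors_connect_under_18_not_6(self):
        assert self._two_voxel_components((0, 0, 0), (0, 1, 1), 18) == 1
        assert self._two_voxel_components((0, 0, 0), (0, 1, 1), 6) == 2

    def test_corner_neighbors_split_under_18_join_under_26(self):
        assert self._two_voxel_components((0, 0, 0), (1, 1, 1), 18) == 2
        assert self._two_voxel_components((0, 0, 0), (1, 1, 1), 26) == 1

    def test_sizes_sum_to_set_voxels(self, rng):
        m = make_mask(rng.random((8, 8, 8)) < 0.3)
        lab = label_components(m, 18)
        assert lab.sizes.sum() == m.n_set

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_partition_matches_flood_fill_oracle(self, connectivity, rng):
        """Labeling agrees with an independent BFS flood fill on random masks."""
        for _ in range(70):
            shape = tuple(rng.integers(3, 13, size=3))
            m = rng.random(shape) < rng.uniform(0.1, 0.6)
            lab = label_components(make_mask(m), connectivity)
            got = partition_from_labels(lab.labels)
            expected = set(flood_fill_components(m, connectivity))
            assert got == expected

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            label_components(make_mask(np.zeros((2, 2, 2), bool)), 10)


class TestFilterSmallClusters:
    def test_boundary_19_removed_20_retained(self):
        # two clusters, sizes 19 and 20, far apart
        m = np.zeros((12, 12, 12), dtype=bool)
        m[0:1, 0:4, 0:5] = True          # 20 voxels
        m[8:9, 8:12, 7:12] = True        # 20 voxels
        m[8, 8, 7] = False               # -> 19 voxels
        lab = label_components(make_mask(m), 18)
        assert sorted(lab.sizes.tolist()) == [19, 20]
        out = filter_small_clusters(lab, 20)
        assert out.n_set == 20
        assert out.data[0, 0, 0] and not out.data[8, 9, 8]

    def test_min_size_one_is_identity(self, rng):
        m = make_mask(rng.random((6, 6, 6)) < 0.4)
        out = filter_small_clusters(label_components(m, 18), 1)
        assert np.array_equal(out.data, m.data)

    def test_all_small_gives_empty_mask(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[0, 0, 0] = m[4, 4, 4] = True
        assert filter_small_clusters(label_components(make_mask(m), 18), 2).n_set == 0

    def test_idempotent(self, rng):
        m = make_mask(rng.random((10, 10, 10)) < 0.35)
        once = filter_small_clusters(label_components(m, 18), 5)
        twice = filter_small_clusters(label_components(once, 18), 5)
        assert np.array_equal(once.data, twice.data)


class TestComputeOverlap:
    def test_identical_masks_score_one(self, rng):
        m = make_mask(rng.random((6, 6, 6)) < 0.4)
        assert m.n_set > 0
        res = compute_overlap(m, m, full_roi((6, 6, 6)))
        assert res.oi == res.dice == res.jaccard == 1.0

    def test_disjoint_masks_score_zero(self):
        shape = (6, 6, 6)
        a = block_mask(shape, (0, 0, 0), (2, 2, 2))
        b = block_mask(shape, (4, 4, 4), (2, 2, 2))
        res = compute_overlap(a, b, full_roi(shape))
        assert res.oi == 0.0 and res.n_overlap == 0

    def test_shifted_block_worked_example(self):
        """3x3x3 block vs the same block shifted by one voxel.

        Expected counts by independent enumeration: 27 voxels each,
        overlap 18, union 36 -> OI = dice = 18/27, jaccard = 0.5,
        overlap size 18/1000 on a 1000-voxel ROI.
        """
        shape = (10, 10, 10)
        a = block_mask(shape, (1, 1, 1), (3, 3, 3))
        b = block_mask(shape, (2, 1, 1), (3, 3, 3))
        # independent voxel enumeration oracle
        vox_a = {(x, y, z) for x in range(1, 4) for y in range(1, 4) for z in range(1, 4)}
        vox_b = {(x + 1, y, z) for (x, y, z) in vox_a}
        assert len(vox_a & vox_b) == 18 and len(vox_a | vox_b) == 36
        res = compute_overlap(a, b, full_roi(shape))
        assert (res.n_b, res.n_f, res.n_overlap, res.n_roi) == (27, 27, 18, 1000)
        assert res.oi == pytest.approx(18 / 27)
        assert res.overlap_size == pytest.approx(0.018)
        assert res.dice == pytest.approx(18 / 27)
        assert res.jaccard == pytest.approx(0.5)

    def test_empty_baseline_undefined_with_reason(self):
        shape = (4, 4, 4)
        empty = make_mask(np.zeros(shape, bool))
        other = block_mask(shape, (0, 0, 0), (2, 2, 2))
        res = compute_overlap(empty, other, full_roi(shape))
        assert res.oi is None and res.undefined_reason == "empty_baseline"
        res2 = compute_overlap(empty, empty, full_roi(shape))
        assert res2.oi is None and res2.undefined_reason == "empty_both"

    def test_empty_roi_rejected(self):
        shape = (4, 4, 4)
        m = block_mask(shape, (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError, match="ROI"):
            compute_overlap(m, m, make_mask(np.zeros(shape, bool)))

    def test_asymmetry_superset_followup(self):
        shape = (8, 8, 8)
        small = block_mask(shape, (1, 1, 1), (2, 2, 2))
        big = block_mask(shape, (1, 1, 1), (4, 4, 4))
        roi = full_roi(shape)
        assert compute_overlap(small, big, roi).oi == 1.0
        assert compute_overlap(big, small, roi).oi < 1.0

    def test_bounds_and_orderings_on_random_masks(self, rng):
        """jaccard <= oi <= 1, jaccard <= dice; oi >= dice iff n_f >= n_b."""
        roi = full_roi((7, 7, 7))
        for _ in range(200):
            a = make_mask(rng.random((7, 7, 7)) < rng.uniform(0.05, 0.6))
            b = make_mask(rng.random((7, 7, 7)) < rng.uniform(0.05, 0.6))
            res = compute_overlap(a, b, roi)
            if res.oi is None:
                continue
            assert 0.0 <= res.oi <= 1.0
            assert res.n_overlap <= min(res.n_b, res.n_f)
            if res.jaccard is not None:
                assert res.jaccard <= res.oi + 1e-12
                assert res.jaccard <= res.dice + 1e-12
            if res.n_f >= res.n_b:
                assert res.oi >= res.dice - 1e-12
            else:
                assert res.oi <= res.dice + 1e-12

    def test_monotone_in_followup_additions(self, rng):
        roi = full_roi((6, 6, 6))
        a = make_mask(rng.random((6, 6, 6)) < 0.3)
        b = make_mask(rng.random((6, 6, 6)) < 0.3)
        if a.n_set == 0:
            a.data[0, 0, 0] = True
        base = compute_overlap(a, b, roi).oi
        b_more = make_mask(b.data | (rng.random((6, 6, 6)) < 0.3))
        assert compute_overlap(a, b_more, roi).oi >= base


class TestComputeOiPair:
    def test_subthreshold_everywhere_is_undefined(self):
        vol = make_volume(np.full((6, 6, 6), 1.0))
        res = compute_oi_pair(vol, vol, full_roi((6, 6, 6)))
        assert res.oi is None and res.undefined_reason == "empty_both"

    def test_persistent_block_scores_one(self):
        shape = (10, 10, 10)
        data = np.full(shape, 1.0)
        data[2:5, 2:5, 2:5] = 1.6     # 27-voxel supra-threshold block
        vol = make_volume(data)
        res = compute_oi_pair(vol, vol, full_roi(shape), OiParams())
        assert res.n_b == 27 and res.oi == 1.0

    def test_shifted_block_through_full_pipeline(self):
        shape = (12, 12, 12)
        b = np.full(shape, 1.0)
        f = np.full(shape, 1.0)
        b[2:5, 2:5, 2:5] = 1.6
        f[3:6, 2:5, 2:5] = 1.6
        res = compute_oi_pair(make_volume(b), make_volume(f), full_roi(shape), OiParams())
        assert res.oi == pytest.approx(18 / 27)

    def test_small_cluster_filtered_before_counting(self):
        shape = (14, 14, 14)
        b = np.full(shape, 1.0)
        b[2:5, 2:5, 2:5] = 1.6       # 27 voxels: survives min_cluster 20
        b[10, 10, 10] = 1.6          # isolated voxel: filtered out
        f = b.copy()
        res = compute_oi_pair(make_volume(b), make_volume(f), full_roi(shape), OiParams())
        assert res.n_b == 27 and res.oi == 1.0
        raw = compute_oi_pair(make_volume(b), make_volume(f), full_roi(shape),
                              OiParams(count_before_filter=True))
        assert raw.n_b == 28 and raw.oi == pytest.approx(27 / 28)

    def test_cluster_filtering_restricted_to_roi(self):
        # supra-threshold voxels outside the ROI must not rescue a small
        # in-ROI cluster across the size filter
        shape = (10, 10, 10)
        data = np.full(shape, 1.0)
        data[0:4, 0:4, 0:2] = 1.6         # 32-voxel cluster, half outside ROI
        roi = np.zeros(shape, dtype=bool)
        roi[0:4, 0:4, 0] = True           # only 16 of them inside
        vol = make_volume(data)
        res = compute_oi_pair(vol, vol, make_mask(roi), OiParams(min_cluster_voxels=20))
        assert res.oi is None             # 16 < 20 inside the ROI

    def test_geometric_invariance_under_axis_permutation_and_flip(self, rng):
        shape = (9, 9, 9)
        b = 1.0 + 0.5 * (rng.random(shape) < 0.2)
        f = 1.0 + 0.5 * (rng.random(shape) < 0.2)
        roi = np.ones(shape, dtype=bool)
        params = OiParams(min_cluster_voxels=3)
        ref = compute_oi_pair(make_volume(b), make_volume(f), make_mask(roi), params)
        for perm in [(1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            tb = np.flip(np.transpose(b, perm), axis=0)
            tf = np.flip(np.transpose(f, perm), axis=0)
            tr = np.flip(np.transpose(roi, perm), axis=0)
            res = compute_oi_pair(make_volume(tb), make_volume(tf), make_mask(tr), params)
            assert res.oi == ref.oi and res.n_b == ref.n_b

    def test_grid_mismatch_rejected(self):
        a = make_volume(np.ones((4, 4, 4)))
        b = make_volume(np.ones((4, 4, 5)))
        with pytest.raises(ValueError, match="common voxel grid"):
            compute_oi_pair(a, b, full_roi((4, 4, 4)))


class TestOiParams:
    @pytest.mark.parametrize("kwargs", [
        {"intensity_threshold": 0.0},
        {"min_cluster_voxels": 0},
        {"connectivity": 10},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OiParams(**kwargs)

    def test_defaults(self):
        p = OiParams()
        assert (p.intensity_threshold, p.min_cluster_voxels, p.connectivity) == (1.4, 20, 18)
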