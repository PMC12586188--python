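"""Seed mapping: correlation, Fisher z, group t, bootstrap consistency."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from interomap.cohort import SubjectTimeSeries, VoxelGrid
from interomap.mapping import (
    BinaryMask,
    ConsistencyMap,
    StatMap,
    binarize_positive,
    bootstrap_consistency,
    clip_r,
    consistency_cutoff,
    consistency_mask,
    extract_seed_timecourse,
    fisher_z,
    group_map,
    group_t,
    masked_group_map,
    seed_matrix,
    seed_zmaps,
    subsample_size,
    voxelwise_r,
)

GRID8 = VoxelGrid((2, 2, 2), 3.0)


def make_ts(data):
    return SubjectTimeSeries("sub-001", np.atleast_2d(data), 1.0, (0,))


class TestSeedTimecourse:
    def test_single_voxel_identity(self, rng):
        ts = make_ts(rng.standard_normal((4, 30)))
        np.testing.assert_array_equal(
            extract_seed_timecourse(ts, [2]), ts.data[2]
        )

    def test_opposite_series_cancel(self, rng):
        s = rng.standard_normal(40)
        ts = make_ts(np.vstack([s, -s]))
        assert np.allclose(extract_seed_timecourse(ts, [0, 1]), 0)

    def test_equals_brute_force_mean(self, rng):
        ts = make_ts(rng.standard_normal((5, 25)))
        roi = [0, 2, 4]
        expected = (ts.data[0] + ts.data[2] + ts.data[4]) / 3
        np.testing.assert_allclose(
            extract_seed_timecourse(ts, roi), expected, atol=1e-12
        )

    def test_empty_roi_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            extract_seed_timecourse(make_ts(rng.standard_normal((2, 10))), [])


class TestVoxelwiseR:
    def test_self_and_negated(self, rng):
        seed = rng.standard_normal(50)
        r, flags = voxelwise_r(np.vstack([seed, -seed]), seed)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert not flags.any()

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = voxelwise_r(a[None, :], b)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert r[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_voxel_flagged_zero(self, rng):
        seed = rng.standard_normal(20)
        r, flags = voxelwise_r(np.vstack([np.full(20, 2.0), seed]), seed)
        assert r[0] == 0.0 and flags[0] and not flags[1]

    def test_constant_seed_rejected(self):
        with pytest.raises(ValueError, match="constant seed"):
            voxelwise_r(np.zeros((2, 10)), np.ones(10))


class TestFisherZ:
    def test_frozen_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @given(st.floats(-0.999, 0.999))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(-0.99, 0.99, 101)
        assert (np.diff(fisher_z(r)) > 0).all()

    def test_clip_keeps_transform_finite(self):
        assert np.isfinite(fisher_z(clip_r(1.0)))
        assert np.isfinite(fisher_z(clip_r(-1.0)))


class TestGroupT:
    def test_frozen_three_subject_case(self):
        t, p, deg = group_t(np.array([0.1, 0.2, 0.3]))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-4)
        assert not deg

    def test_all_zeros(self):
        t, p, deg = group_t(np.zeros(5))
        assert t == 0.0 and p == 1.0 and not deg

    def test_zero_variance_nonzero_mean_flagged(self):
        t, p, deg = group_t(np.full(4, 0.3))
        assert p == 0.0 and deg and np.isinf(t)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_t(np.array([0.1, 0.2]))

    def test_matches_scipy_on_random_arrays(self, rng):
        z = rng.standard_normal((10, 40))
        t, p, _ = group_t(z)
        ref = stats.ttest_1samp(z, 0.0, axis=0)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)


class TestBinarize:
    def make_map(self, t, p):
        return StatMap(GRID8, np.zeros(8), np.zeros(8), np.asarray(t), np.asarray(p), 10)

    def test_all_negative_empty(self):
        m = self.make_map(-np.ones(8), np.full(8, 0.001))
        assert binarize_positive(m, 0.05).n_voxels == 0

    def test_alpha_one_keeps_all_positive(self):
        t = np.array([1.0, -1, 1, -1, 1, 1, -1, 1])
        m = self.make_map(t, np.full(8, 0.5))
        assert binarize_positive(m, 1.0).n_voxels == (t > 0).sum()

    def test_matches_set_comprehension(self, rng):
        t = rng.standard_normal(8)
        p = rng.uniform(size=8)
        m = self.make_map(t, p)
        expected = {i for i in range(8) if p[i] < 0.05 and t[i] > 0}
        assert set(binarize_positive(m, 0.05).indices) == expected


class TestBootstrapConsistency:
    def test_study_scale_constants(self):
        assert subsample_size(90, 0.8) == 72
        assert consistency_cutoff(1000, 0.95) == 950

    def test_degenerate_single_full_iteration(self, rng):
        z = rng.standard_normal((8, 50))
        counts = bootstrap_consistency(z, B=1, fraction=1.0, rng_seed=0)
        t, p, _ = group_t(z)
        np.testing.assert_array_equal(counts, ((p < 0.05) & (t > 0)).astype(int))

    def test_equals_nested_loop_reference(self, rng):
        """Vectorized counts match an independent per-voxel scipy loop that
        consumes the identical rng subsample stream."""
        n_sub, n_vox, B, f = 5, 50, 50, 0.8
        z = rng.standard_normal((n_sub, n_vox)) + 0.3
        counts = bootstrap_consistency(z, B=B, fraction=f, alpha=0.05, rng_seed=42)
        ref_rng = np.random.default_rng(42)
        m = int(np.floor(f * n_sub))
        expected = np.zeros(n_vox, dtype=int)
        for _ in range(B):
            idx = ref_rng.choice(n_sub, size=m, replace=False)
            for v in range(n_vox):
                res = stats.ttest_1samp(z[idx, v], 0.0)
                if res.pvalue < 0.05 and res.statistic > 0:
                    expected[v] += 1
        np.testing.assert_array_equal(counts, expected)

    def test_null_voxel_survival_near_alpha_half(self, rng):
        """Pure-noise voxels pass (positive, p < 0.05) in ~2.5% of
        iterations: expected count ~25 of B = 1000."""
        z = rng.standard_normal((12, 300))
        counts = bootstrap_consistency(z, B=1000, fraction=0.8, rng_seed=3)
        assert 18 < counts.mean() < 32

    def test_subsample_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_consistency(rng.standard_normal((3, 5)), B=2, fraction=0.5)

    def test_reproducible(self, rng):
        z = rng.standard_normal((6, 20))
        a = bootstrap_consistency(z, B=20, rng_seed=9)
        b = bootstrap_consistency(z, B=20, rng_seed=9)
        np.testing.assert_array_equal(a, b)


class TestConsistencyMask:
    def make_cmap(self, counts, B=1000):
        return ConsistencyMap(GRID8, np.asarray(counts), B, 0.8, 0.05)

    def test_strict_cutoff_boundary(self):
        counts = [949, 950, 951, 1000, 0, 500, 950, 951]
        mask = consistency_mask(self.make_cmap(counts), 950)
        assert set(mask.indices) == {2, 3, 7}

    def test_min_count_b_gives_empty(self):
        mask = consistency_mask(self.make_cmap([1000] * 8), 1000)
        assert mask.n_voxels == 0

    def test_masks_nested_in_cutoff(self, rng):
        counts = rng.integers(0, 1001, size=8)
        loose = consistency_mask(self.make_cmap(counts), 900)
        tight = consistency_mask(self.make_cmap(counts), 950)
        assert set(tight.indices) <= set(loose.indices)


class TestMaskedGroupMap:
    def make_map(self, rng):
        t = rng.standard_normal(8)
        return StatMap(GRID8, t, t, t, rng.uniform(size=8), 12)

    def test_full_mask_identity(self, rng):
        m = self.make_map(rng)
        out = masked_group_map(m, BinaryMask(GRID8, np.ones(8, bool)))
        np.testing.assert_array_equal(out.t, m.t)

    def test_empty_mask_nulls_all(self, rng):
        out = masked_group_map(self.make_map(rng), BinaryMask(GRID8, np.zeros(8, bool)))
        assert (out.t == 0).all() and (out.p == 1).all()

    def test_composition_matches_restriction(self, rng):
        m = self.make_map(rng)
        keep = np.array([1, 0, 1, 0, 0, 1, 1, 0], bool)
        out = masked_group_map(m, BinaryMask(GRID8, keep))
        np.testing.assert_array_equal(out.t[keep], m.t[keep])
        assert (out.t[~keep] == 0).all()


class TestSeedMatrix:
    def test_diagonal_sentinel_and_symmetry(self, tiny_cohort):
        _, rois, cohort, _ = tiny_cohort
        labels = rois.cortical_labels
        m = seed_matrix(cohort, rois, labels=labels)
        assert np.isnan(np.diagonal(m.z, axis1=1, axis2=2)).all()
        off = ~np.eye(len(labels), dtype=bool)
        np.testing.assert_array_equal(m.t[off], m.t.T[off])
        np.testing.assert_array_equal(m.p[off], m.p.T[off])
        # per-subject correlation of a seed with itself is 1 by construction
        tc = cohort[0].data[rois.members[labels[0]]].mean(axis=0)
        assert np.corrcoef(tc, tc)[0, 1] == pytest.approx(1.0)

    def test_label_permutation_equivariance(self, tiny_cohort):
        _, rois, cohort, _ = tiny_cohort
        labels = rois.cortical_labels
        m1 = seed_matrix(cohort, rois, labels=labels)
        perm = labels[::-1]
        m2 = seed_matrix(cohort, rois, labels=perm)
        idx = [labels.index(l) for l in perm]
        np.testing.assert_allclose(m2.t, m1.t[np.ix_(idx, idx)], atol=1e-12)

    def test_same_network_seeds_significant(self, tiny_cohort):
        _, rois, cohort, _ = tiny_cohort
        m = seed_matrix(cohort, rois)
        assert m.significant_positive("sgACC", "pACC")

    def test_constant_seed_named_in_error(self, grid_rois):
        grid, rois = grid_rois
        data = np.zeros((grid.n_voxels, 20))
        data[:, :] = np.random.default_rng(0).standard_normal((grid.n_voxels, 20))
        data[rois.members["sgACC"]] = 5.0
        cohort = [SubjectTimeSeries(f"sub-{i:03d}", data, 1.0, (0,)) for i in range(3)]
        with pytest.raises(ValueError, match="sgACC"):
            seed_matrix(cohort, rois, labels=rois.cortical_labels)


def test_group_map_statistics_consistent(tiny_cohort):
    grid, rois, cohort, _ = tiny_cohort
    z = seed_zmaps(cohort, rois, ["sgACC"])
    m = group_map(z[:, 0], grid)
    assert m.n_subjects == len(cohort) and m.df == len(cohort) - 1
    assert ((m.p >= 0) & (m.p <= 1)).all()
    # the seed's own voxels must be strongly positive
    own = rois.members["sgACC"]
    assert (m.t[own] > 5).all()
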