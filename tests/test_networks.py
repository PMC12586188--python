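"""Conjunctions, eta-squared similarity, k-means/CH selection, Dice."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from interomap.cohort import (
    DEFAULT_CLUSTER_OF_SEED,
    DEFAULT_NETWORK_OF_SEED,
    GroundTruth,
    RoiSpec,
    SimConfig,
    VoxelGrid,
    build_grid_rois,
    default_ground_truth,
    simulate_cohort,
)
from interomap.conditioning import condition_subject
from interomap.mapping import BinaryMask, group_map, seed_zmaps
from interomap.networks import (
    cluster_conjunctions,
    conjunction,
    connecting_regions,
    dice,
    dice_permutation_test,
    eta_squared,
    kmeans_over_k,
    similarity_matrix,
)

GRID = VoxelGrid((2, 2, 2), 3.0)


def mask(bits):
    return BinaryMask(GRID, np.asarray(bits, bool))


class TestConjunction:
    def test_identical_masks_count_k(self):
        m = mask([1, 0, 1, 0, 0, 0, 1, 0])
        c = conjunction([m, m, m])
        assert set(np.unique(c.counts)) <= {0, 3}
        assert (c.counts[m.indices] == 3).all()

    def test_disjoint_masks_max_one(self):
        c = conjunction([mask([1, 0, 0, 0, 0, 0, 0, 0]), mask([0, 1, 0, 0, 0, 0, 0, 0])])
        assert c.counts.max() == 1

    def test_matches_per_voxel_sum(self, rng):
        ms = [mask(rng.integers(0, 2, 8)) for _ in range(3)]
        c = conjunction(ms)
        np.testing.assert_array_equal(c.counts, sum(m.data.astype(int) for m in ms))

    def test_grid_mismatch_rejected(self):
        other = BinaryMask(VoxelGrid((1, 2, 2), 3.0), np.ones(4, bool))
        with pytest.raises(ValueError, match="grid"):
            conjunction([mask([1] * 8), other])


class TestConnectingRegions:
    def test_min_overlap_one_is_union(self, rng):
        ms = [mask(rng.integers(0, 2, 8)) for _ in range(4)]
        c = conjunction(ms)
        union = np.logical_or.reduce([m.data for m in ms])
        np.testing.assert_array_equal(connecting_regions(c, 1).data, union)

    def test_full_conjunction_of_disjoint_empty(self):
        c = conjunction([mask([1, 0, 0, 0, 0, 0, 0, 0]), mask([0, 0, 1, 0, 0, 0, 0, 0])])
        assert connecting_regions(c).n_voxels == 0

    def test_nesting_in_min_overlap(self, rng):
        ms = [mask(rng.integers(0, 2, 8)) for _ in range(5)]
        c = conjunction(ms)
        prev = connecting_regions(c, 1)
        for k in range(2, 6):
            cur = connecting_regions(c, k)
            assert set(cur.indices) <= set(prev.indices)
            prev = cur


class TestEtaSquared:
    def test_identical_maps_exactly_one(self, rng):
        a = rng.standard_normal(30)
        assert eta_squared(a, a) == 1.0

    def test_antisymmetric_zero_mean_gives_zero(self, rng):
        a = rng.standard_normal(40)
        a -= a.mean()
        assert eta_squared(a, -a) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_hand_computed_value(self):
        assert eta_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.926829, abs=1e-6)

    def test_equal_constant_maps_defined_one(self):
        assert eta_squared([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_unequal_constant_maps(self):
        # all variance is within voxel pairs -> similarity 0
        assert eta_squared([1.0, 1.0], [3.0, 3.0]) == pytest.approx(0.0)

    @given(
        hnp.arrays(np.float64, 12, elements=st.floats(-5, 5)),
        hnp.arrays(np.float64, 12, elements=st.floats(-5, 5)),
    )
    def test_symmetric_and_bounded(self, a, b):
        v = eta_squared(a, b)
        w = eta_squared(b, a)
        if np.isnan(v):
            assert np.isnan(w)
        else:
            assert v == pytest.approx(w, abs=1e-10)
            assert -1e-9 <= v <= 1 + 1e-9


class TestSimilarityMatrix:
    def test_identical_maps_all_ones(self, rng):
        a = rng.standard_normal(20)
        s = similarity_matrix(np.vstack([a, a]), ["x", "y"])
        np.testing.assert_allclose(s.values, 1.0)

    def test_permutation_equivariance(self, rng):
        maps = rng.standard_normal((4, 25))
        s1 = similarity_matrix(maps, list("abcd"))
        order = [2, 0, 3, 1]
        s2 = similarity_matrix(maps[order], [list("abcd")[i] for i in order])
        np.testing.assert_allclose(s2.values, s1.values[np.ix_(order, order)], atol=1e-12)

    def test_matches_per_pair_evaluation(self, rng):
        maps = rng.standard_normal((3, 15))
        s = similarity_matrix(maps, list("abc"))
        for i, j in itertools.combinations(range(3), 2):
            assert s.values[i, j] == pytest.approx(eta_squared(maps[i], maps[j]))


def best_partition_ch(X, k):
    """Brute-force oracle: enumerate all partitions of the rows of X into
    exactly k non-empty blocks (restricted growth strings), take the
    partition minimizing the within-cluster sum of squares, and return its
    Calinski-Harabasz score and labels."""
    n = len(X)

    def partitions(i, labels, used):
        if i == n:
            if used == k:
                yield tuple(labels)
            return
        for c in range(min(used + 1, k)):
            labels.append(c)
            yield from partitions(i + 1, labels, max(used, c + 1))
            labels.pop()

    best = None
    for labels in partitions(0, [], 0):
        lab = np.asarray(labels)
        w = 0.0
        for c in range(k):
            pts = X[lab == c]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        if best is None or w < best[0]:
            best = (w, lab)
    w, lab = best
    grand = X.mean(axis=0)
    b = sum(
        (lab == c).sum() * ((X[lab == c].mean(axis=0) - grand) ** 2).sum()
        for c in range(k)
    )
    ch = (b / (k - 1)) / (w / (n - k))
    return ch, lab


class TestKMeansSelection:
    def test_two_blocks_of_identical_rows(self):
        """Perfectly separable duplicate blocks: every k splits them with
        zero scatter, so the smallest-k tie-break selects k = 2."""
        X = np.vstack([np.tile([0.0, 0.0], (4, 1)), np.tile([8.0, 8.0], (4, 1))])
        sol = kmeans_over_k(X, range(2, 7), rng_seed=0)
        assert sol.chosen_k == 2
        labels = np.array([sol.labels[str(i)] for i in range(8)])
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_chosen_k_matches_partition_oracle_on_three_blobs(self, rng):
        """12 planar points in 3 separated blobs: CH selection over k = 2..3
        and the winning labels agree with the exhaustive best-partition
        oracle (all set partitions enumerated)."""
        centers = np.array([[0, 0], [10, 0], [5, 9]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.8, (4, 2)) for c in centers])
        sol = kmeans_over_k(X, range(2, 4), restarts=10, rng_seed=1)
        oracle = {k: best_partition_ch(X, k) for k in (2, 3)}
        assert sol.chosen_k == 3
        assert oracle[3][0] > oracle[2][0]
        for k in (2, 3):
            ch, lab = oracle[k]
            assert sol.ch_scores[k] == pytest.approx(ch, rel=1e-6)
            ours = np.array([sol.labels_by_k[k][str(i)] for i in range(12)])
            # same partition up to relabelling
            assert len({(a, b) for a, b in zip(ours, lab)}) == k

    def test_k_at_least_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_over_k(rng.standard_normal((4, 2)), range(2, 5))

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((9, 3))
        a = kmeans_over_k(X, range(2, 5), rng_seed=5)
        b = kmeans_over_k(X, range(2, 5), rng_seed=5)
        assert a.chosen_k == b.chosen_k and a.labels == b.labels


class TestClusterConjunctions:
    def test_singleton_cluster_is_own_mask(self):
        m = mask([1, 1, 0, 0, 0, 0, 0, 0])
        out = cluster_conjunctions({"a": m}, {"a": 1})
        np.testing.assert_array_equal(out[1].data, m.data)

    def test_nested_masks_give_smallest(self):
        big = mask([1, 1, 1, 1, 0, 0, 0, 0])
        small = mask([1, 1, 0, 0, 0, 0, 0, 0])
        out = cluster_conjunctions({"a": big, "b": small}, {"a": 1, "b": 1})
        np.testing.assert_array_equal(out[1].data, small.data)

    def test_matches_direct_intersection(self, rng):
        ms = {n: mask(rng.integers(0, 2, 8)) for n in "abc"}
        out = cluster_conjunctions(ms, {"a": 1, "b": 1, "c": 2})
        np.testing.assert_array_equal(out[1].data, ms["a"].data & ms["b"].data)
        np.testing.assert_array_equal(out[2].data, ms["c"].data)


class TestDice:
    def test_identical(self):
        m = mask([1, 0, 1, 0, 1, 0, 0, 0])
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        assert dice(mask([1, 1, 0, 0, 0, 0, 0, 0]), mask([0, 0, 1, 1, 0, 0, 0, 0])) == 0.0

    def test_half_overlap_formula(self):
        a = np.zeros(20, bool)
        b = np.zeros(20, bool)
        a[:10] = True
        b[5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_zero(self):
        assert dice(np.zeros(8, bool), np.zeros(8, bool)) == 0.0


class TestDicePermutation:
    def make_parcellation(self, n_parcels=10, parcel_size=6, n_labels=5):
        ids = np.repeat(np.arange(1, n_parcels + 1), parcel_size)
        labels = {pid: (pid - 1) % n_labels + 1 for pid in range(1, n_parcels + 1)}
        return ids, labels

    def test_mask_equal_to_one_parcel_among_many_is_significant(self):
        """A mask coinciding with one parcel of a many-parcel parcellation
        sits at the extreme of the permutation null for its label."""
        ids, labels = self.make_parcellation(n_parcels=300, parcel_size=2, n_labels=300)
        m = ids == 1
        res = dice_permutation_test(m, ids, labels, n_perm=199, rng_seed=0)
        row = res.loc[res["label"] == labels[1]].iloc[0]
        assert row["dice"] == pytest.approx(1.0)
        assert row["p"] <= 0.05

    def test_min_p_bounded_by_permutation_count(self):
        ids, labels = self.make_parcellation()
        res = dice_permutation_test(ids == 1, ids, labels, n_perm=99, rng_seed=0)
        assert (res["p"] >= 1 / 100 - 1e-12).all()

    def test_single_label_rejected(self):
        ids = np.repeat([1, 2], 5)
        with pytest.raises(ValueError, match="label"):
            dice_permutation_test(np.ones(10, bool), ids, {1: 1, 2: 1}, n_perm=99)

    def test_too_few_permutations_rejected(self):
        ids, labels = self.make_parcellation()
        with pytest.raises(ValueError):
            dice_permutation_test(ids == 1, ids, labels, n_perm=10)

    def test_null_rejection_rate_calibrated(self, rng):
        """Masks built from random parcel subsets (no label preference)
        reject at ~alpha under the permutation null."""
        ids, labels = self.make_parcellation(n_parcels=12, parcel_size=5, n_labels=4)
        rejections = 0
        trials = 0
        for rep in range(120):
            chosen = rng.choice(np.arange(1, 13), size=4, replace=False)
            m = np.isin(ids, chosen)
            res = dice_permutation_test(m, ids, labels, n_perm=99, rng_seed=rep)
            rejections += int((res["p"] <= 0.05).sum())
            trials += len(res)
        rate = rejections / trials
        # binomial 99.7% bounds around 0.05 for ~480 dependent-ish trials
        assert 0.01 <= rate <= 0.10


class TestClusterRecovery:
    def _group_maps(self, rois, cohort, labels, grid):
        z = seed_zmaps(cohort, rois, labels)
        return np.stack([group_map(z[:, i], grid).t for i in range(len(labels))])

    def test_cortical_two_network_recovery(self):
        """Planted two-network cortical cohorts: CH selects k = 2 and the
        k-means labels match the planted networks (ARI ~ 1)."""
        from sklearn.metrics import adjusted_rand_score

        spec = RoiSpec(subcortical_sizes=())
        grid, rois = build_grid_rois((16, 16, 16), spec, rng_seed=1)
        gt = GroundTruth(network_loadings=default_ground_truth().network_loadings)
        cfg = SimConfig(n_subjects=12, n_runs=2, frames_per_run=100)
        aris, ks = [], []
        for rep in range(6):
            cohort, confs = simulate_cohort(grid, rois, gt, cfg, rng_seed=50 + rep)
            cohort = [condition_subject(ts, c)[0] for ts, c in zip(cohort, confs)]
            maps = self._group_maps(rois, cohort, rois.labels, grid)
            sol = kmeans_over_k(similarity_matrix(maps, rois.labels), range(2, 7),
                                rng_seed=rep)
            ks.append(sol.chosen_k)
            truth = [DEFAULT_NETWORK_OF_SEED[l] for l in rois.labels]
            found = [sol.labels_by_k[2][l] for l in rois.labels]
            aris.append(adjusted_rand_score(truth, found))
        assert np.mean(aris) >= 0.9
        assert ks.count(2) >= 5

    def test_subcortical_three_cluster_recovery(self):
        """Three planted projection-profile groups (small lower brainstem,
        upper brainstem + hypothalamus, large nuclei) recovered at k = 3."""
        from sklearn.metrics import adjusted_rand_score

        grid, rois = build_grid_rois((16, 16, 16), rng_seed=1)
        gt = default_ground_truth()
        cfg = SimConfig(n_subjects=12, n_runs=2, frames_per_run=100)
        subs = rois.subcortical_labels
        aris = []
        for rep in range(6):
            cohort, confs = simulate_cohort(grid, rois, gt, cfg, rng_seed=70 + rep)
            cohort = [condition_subject(ts, c)[0] for ts, c in zip(cohort, confs)]
            maps = self._group_maps(rois, cohort, subs, grid)
            sol = kmeans_over_k(similarity_matrix(maps, subs), range(2, 10),
                                rng_seed=rep)
            truth = [DEFAULT_CLUSTER_OF_SEED[l] for l in subs]
            found = [sol.labels_by_k[3][l] for l in subs]
            aris.append(adjusted_rand_score(truth, found))
        assert np.mean(aris) >= 0.9
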