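import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import chi2

import tractlabel as tl
from tractlabel import (
    GroupingParams,
    ValidationError,
    align_group_orientations,
    group_subject,
    grouping_consistency,
    hierarchical_cluster,
    kmeans_length_partition,
    merge_length_ranges,
    remove_outliers,
)
from tractlabel.grouping import TractGroup, _outlier_size_threshold
from tractlabel.tract_model import TractSet, resample_tract


def point_tract_vectors(xs):
    """Single-sample-point tract vectors: flip-invariant distance reduces to
    plain 1-D distance, letting tests prescribe exact pairwise distances."""
    return np.array([[x, 0.0, 0.0] for x in xs])


def straight_tract(x0, length=50.0, n=16, y=0.0):
    pts = np.array([[x0, y, 0.0], [x0, y, length]])
    return resample_tract(pts, n)


def brute_force_1d_kmeans(lengths, k):
    """Exhaustive minimization of within-cluster SSE over contiguous splits
    of sorted 1-D data (optimal 1-D clustering is contiguous)."""
    xs = np.sort(lengths)
    n = len(xs)
    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = xs[a:b]
            cost += ((seg - seg.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best = cost, bounds
    labels = np.empty(n, dtype=int)
    for j, (a, b) in enumerate(zip(best[:-1], best[1:])):
        labels[a:b] = j
    order = np.argsort(np.argsort(lengths, kind="stable"), kind="stable")
    return labels[np.argsort(np.argsort(lengths))], best_cost


class TestKMeansLengthPartition:
    def test_well_separated_clusters(self):
        lengths = np.array([20.0, 21, 22, 100, 101, 102])
        assert np.array_equal(
            kmeans_length_partition(lengths, 2), [0, 0, 0, 1, 1, 1]
        )

    def test_k1_puts_everything_in_range_zero(self):
        assert np.array_equal(
            kmeans_length_partition(np.array([5.0, 50, 500]), 1), [0, 0, 0]
        )

    def test_matches_brute_force_oracle(self):
        lengths = np.array([10.0, 20, 30, 40, 50, 60])
        got = kmeans_length_partition(lengths, 3)
        expected, expected_cost = brute_force_1d_kmeans(lengths, 3)
        cost = sum(
            ((lengths[got == j] - lengths[got == j].mean()) ** 2).sum()
            for j in range(3)
        )
        assert cost == pytest.approx(expected_cost)

    def test_ranges_ordered_by_centroid(self):
        lengths = np.array([100.0, 101, 20, 21, 60, 61])
        labels = kmeans_length_partition(lengths, 3)
        assert labels[2] == 0 and labels[4] == 1 and labels[0] == 2

    def test_k_reduced_with_warning(self):
        with pytest.warns(UserWarning):
            labels = kmeans_length_partition(np.array([1.0, 1.0, 2.0]), 3)
        assert len(set(labels)) == 2

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            kmeans_length_partition(np.array([]), 2)


class TestHierarchicalCluster:
    def test_pair_below_threshold_merges(self):
        v = point_tract_vectors([0.0, 39.0])
        assert len(hierarchical_cluster(v, 40.0)) == 1

    def test_pair_above_threshold_stays_split(self):
        v = point_tract_vectors([0.0, 41.0])
        assert len(hierarchical_cluster(v, 40.0)) == 2

    def test_average_linkage_three_points(self):
        # d(A,B)=10, d(A,C)=d(B,C)=50: after merging A,B the average
        # distance to C is 50 > 40, so C stays apart
        v = point_tract_vectors([0.0, 10.0, -40.0])
        clusters = sorted(hierarchical_cluster(v, 40.0), key=len, reverse=True)
        assert sorted(map(len, clusters)) == [1, 2]
        assert set(clusters[0]) == {0, 1}

    def test_threshold_monotonicity(self, rng):
        v = rng.uniform(0, 100, size=(30, 6))
        counts = [len(hierarchical_cluster(v, t)) for t in (10.0, 40.0, 160.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(point_tract_vectors([0.0]), 0.0)


class TestAlignGroupOrientations:
    def test_co_oriented_unchanged(self):
        members = np.array([[0.0, 0, 0, 1, 0, 0], [0.1, 0, 0, 1.1, 0, 0]])
        assert np.array_equal(align_group_orientations(members), members)

    def test_reversed_member_is_flipped(self):
        ref = np.array([0.0, 0, 0, 10, 0, 0])
        stored_reversed = np.array([10.0, 0, 0, 0, 0, 0])
        out = align_group_orientations(np.array([ref, stored_reversed]))
        assert np.array_equal(out[1], ref)

    def test_tie_keeps_stored_orientation(self):
        ref = np.array([0.0, 0, 0, 0, 0, 0])
        palindrome_tie = np.array([1.0, 0, 0, -1.0, 0, 0])
        out = align_group_orientations(np.array([ref, palindrome_tie]))
        assert np.array_equal(out[1], palindrome_tie)


class TestMergeLengthRanges:
    def make_groups(self, vectors, split):
        return [
            [TractGroup(member_indices=np.array(idx), length_range_id=r)
             for idx in groups]
            for r, groups in enumerate(split)
        ]

    def test_identical_mean_curves_merge(self):
        v = np.array([[0.0, 0, 0], [0.0, 0, 0], [50.0, 0, 0]])
        by_range = self.make_groups(v, [[[0]], [[1], [2]]])
        merged = merge_length_ranges(by_range, v, 20.0)
        sizes = sorted(g.size for g in merged)
        assert sizes == [1, 2]

    def test_distance_21_not_merged_at_20(self):
        v = point_tract_vectors([0.0, 21.0])
        by_range = self.make_groups(v, [[[0]], [[1]]])
        merged = merge_length_ranges(by_range, v, 20.0)
        assert len(merged) == 2

    def test_transitive_merge_within_cluster(self):
        # pairwise mean-curve distances 5, 5, 8 -> single average-linkage
        # cluster at threshold 20 -> one merged group
        v = point_tract_vectors([0.0, 5.0, 8.0])
        by_range = self.make_groups(v, [[[0], [1]], [[2]]])
        merged = merge_length_ranges(by_range, v, 20.0)
        assert len(merged) == 1 and merged[0].size == 3

    def test_empty_ranges_skipped(self):
        v = point_tract_vectors([0.0])
        by_range = self.make_groups(v, [[[0]], []])
        merged = merge_length_ranges(by_range, v, 20.0)
        assert len(merged) == 1


class TestRemoveOutliers:
    def test_size_threshold_respects_mass_fraction(self):
        # sizes {1,1,2,50,60}: flagged mass at t=2 is 2 <= 2.28, at t=3 is 4
        sizes = np.array([1, 1, 2, 50, 60])
        assert _outlier_size_threshold(sizes, 0.02) == 2

    def _toy_grouping(self):
        rng = np.random.default_rng(3)
        vecs = []
        vecs.extend(rng.normal([0, 0, 0, 40, 0, 0], 1.0, (60, 6)))
        vecs.extend(rng.normal([200, 0, 0, 260, 0, 0], 1.0, (52, 6)))
        vecs.append(np.array([0.0, 0, 0, 40, 0, 0]))       # equals group mean-ish
        vecs.append(np.array([5000.0, 0, 0, 5100, 0, 0]))  # far from everything
        vecs = np.array(vecs)
        tracts = [resample_tract(v.reshape(2, 3), 2) for v in vecs]
        ts = TractSet(tracts=tracts)
        groups = [
            TractGroup(member_indices=np.arange(60)),
            TractGroup(member_indices=np.arange(60, 112)),
            TractGroup(member_indices=np.array([112])),
            TractGroup(member_indices=np.array([113])),
        ]
        return ts, groups

    def test_reassignment_and_rejection(self):
        ts, groups = self._toy_grouping()
        params = GroupingParams()
        result = remove_outliers(groups, ts, params)
        assert len(result.groups) == 2
        # near tract reassigned into the big group, far tract dropped
        assert 112 in np.concatenate(result.partition())
        assert np.array_equal(result.removed_outlier_indices, [113])

    def test_rejection_uses_chi_square_critical_value(self):
        ts, groups = self._toy_grouping()
        critical = chi2.ppf(0.98, df=6)
        from tractlabel.bundle_stats import tract_group_distance
        from tractlabel.grouping import _fit_group_model

        model = _fit_group_model(ts.vectors(), np.arange(60))
        assert tract_group_distance(ts.vectors()[113], model) > critical

    def test_mass_rule_never_flags_every_group(self, rng):
        # the threshold rule keeps at least the largest group for any
        # admissible mass fraction, so the no-survivor guard is defensive
        for _ in range(50):
            sizes = rng.integers(1, 50, size=rng.integers(1, 10))
            t = _outlier_size_threshold(sizes, 0.5)
            assert np.any(sizes >= t)


@pytest.fixture(scope="module")
def three_bundle_subject():
    spec = tl.SyntheticCohortSpec(
        templates=tl.default_templates()[:3],
        n_subjects=1, tracts_per_bundle=50, shape_noise_sd=1.0,
        subject_affine_jitter=tl.AffineJitter(0, 0, 0),
        outlier_fraction=0.0, seed=11,
    )
    return tl.sample_subject(spec, 0)


class TestGroupSubject:
    def test_bundles_never_split_across_groups(self, three_bundle_subject):
        ts, labels, _ = three_bundle_subject
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = group_subject(ts)
        assert len(result.groups) >= 3
        for g in result.groups:
            assert len(set(labels[g.member_indices])) == 1

    def test_deterministic_across_runs(self, three_bundle_subject):
        ts, _, _ = three_bundle_subject
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = group_subject(ts)
            b = group_subject(ts)
        assert len(a.groups) == len(b.groups)
        for ga, gb in zip(a.groups, b.groups):
            assert np.array_equal(ga.member_indices, gb.member_indices)

    def test_single_tract_becomes_singleton_group(self):
        t = resample_tract(np.array([[0.0, 0, 0], [50.0, 0, 0]]), 32)
        result = group_subject(TractSet(tracts=[t]))
        assert len(result.groups) == 1 and result.groups[0].size == 1
        assert len(result.removed_outlier_indices) == 0

    def test_partition_property(self, three_bundle_subject):
        ts, _, _ = three_bundle_subject
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = group_subject(ts)
        covered = np.sort(
            np.concatenate(result.partition() + [result.removed_outlier_indices])
        )
        assert np.array_equal(covered, np.arange(len(ts)))


class TestGroupingConsistency:
    def test_identical_partitions(self):
        p = [np.arange(5), np.arange(5, 9)]
        assert grouping_consistency(p, p) == 100.0

    def test_refinement_is_asymmetric(self):
        coarse = [np.arange(10)]
        fine = [np.arange(5), np.arange(5, 10)]
        assert grouping_consistency(coarse, fine) == 50.0
        assert grouping_consistency(fine, coarse) == 100.0

    def test_different_universes_raise(self):
        with pytest.raises(ValidationError):
            grouping_consistency([np.arange(5)], [np.arange(6)])
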