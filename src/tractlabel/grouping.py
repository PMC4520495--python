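"""Scalable shape clustering of a subject's tracts.

Direct average-linkage hierarchical clustering of a whole-brain tractogram
needs a pairwise distance table that does not fit in memory.  The pipeline
therefore runs in four stages:

1. 1-D k-means partitions the tracts into length ranges (default 100) by
   chord length;
2. within each range, agglomerative average-linkage clustering under the
   flip-invariant distance, cut at a distance threshold (default 40 mm);
3. groups in consecutive length ranges whose orientation-aligned mean curves
   fall within a tighter threshold (default 20 mm) are merged, sweeping the
   ranges in ascending order;
4. groups holding less than ~2% of the total tract mass are flagged as
   outlier groups; their tracts are reassigned to the closest surviving
   Gaussian group if the flip-invariant Mahalanobis value is below the
   chi-square critical value, and dropped otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from .bundle_stats import GaussianGroupModel, group_mean, tract_group_distance
from .errors import ConfigurationError, ValidationError
from .tract_model import TractSet, euclidean_distance, pairwise_tract_distances, reverse_vector

# Below this many tracts the 2%-mass outlier rule is meaningless and the
# outlier stage is skipped entirely.
MIN_TRACTS_FOR_OUTLIER_STAGE = 50


@dataclass
class GroupingParams:
    """Tunable parameters of the tract-grouping pipeline."""

    n_length_ranges: int = 100
    hier_threshold: float = 40.0        # mm, within-range average-linkage cut
    merge_threshold: float = 20.0       # mm, cross-range mean-curve cut
    outlier_mass_fraction: float = 0.02
    chi2_level: float = 0.02            # upper-tail level for tract rejection
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hier_threshold <= 0 or self.merge_threshold <= 0:
            raise ValidationError("distance thresholds must be positive")
        if not (0 < self.outlier_mass_fraction < 1):
            raise ValidationError("outlier_mass_fraction must be in (0, 1)")
        if not (0 < self.chi2_level < 1):
            raise ValidationError("chi2_level must be in (0, 1)")
        if self.n_length_ranges < 1:
            raise ValidationError("n_length_ranges must be >= 1")


@dataclass
class TractGroup:
    """A shape-homogeneous set of tracts (indices into a TractSet)."""

    member_indices: np.ndarray
    length_range_id: int = 0
    is_outlier_group: bool = False
    model: GaussianGroupModel | None = None

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class GroupingResult:
    """Partition of a tract set into groups plus removed outlier tracts."""

    groups: list[TractGroup]
    removed_outlier_indices: np.ndarray
    params_used: GroupingParams

    def partition(self) -> list[np.ndarray]:
        """Member-index arrays of the non-removed groups."""
        return [g.member_indices for g in self.groups]

    def labels(self, n_tracts: int) -> np.ndarray:
        """Per-tract group id; removed outliers get -1."""
        out = np.full(n_tracts, -1, dtype=int)
        for gid, g in enumerate(self.groups):
            out[g.member_indices] = gid
        return out


def _check_partition(groups: list[TractGroup], removed: np.ndarray, n: int) -> None:
    seen = np.concatenate([g.member_indices for g in groups] + [removed]) if groups else removed
    if len(seen) != n or len(np.unique(seen)) != n:
        raise ValidationError("groups + removed outliers do not partition the tract set")


def kmeans_length_partition(
    lengths: np.ndarray, k: int, seed: int | None = None
) -> np.ndarray:
    """1-D k-means on chord lengths; range ids ordered by ascending centroid.

    Deterministic: centroids start at k evenly spread values of the sorted
    distinct lengths and Lloyd iterations run to a 1e-9 relative tolerance
    (``seed`` is accepted for interface symmetry but unused).
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValidationError("no lengths to partition")
    if k < 1:
        raise ValidationError("k must be >= 1")
    distinct = np.unique(lengths)
    if k > distinct.size:
        warnings.warn(
            f"reducing k from {k} to {distinct.size} distinct lengths", stacklevel=2
        )
        k = distinct.size
    if k == 1:
        return np.zeros(lengths.size, dtype=int)

    centroids = distinct[np.round(np.linspace(0, distinct.size - 1, k)).astype(int)]
    order = np.argsort(lengths)
    sorted_lengths = lengths[order]
    for _ in range(500):
        # assignment: nearest centroid == searchsorted on midpoints
        mids = 0.5 * (centroids[:-1] + centroids[1:])
        assign = np.searchsorted(mids, sorted_lengths)
        new = centroids.copy()
        for j in range(k):
            sel = sorted_lengths[assign == j]
            if sel.size:
                new[j] = sel.mean()
        shift = np.abs(new - centroids).max()
        centroids = np.sort(new)
        if shift <= 1e-9 * max(1.0, np.abs(centroids).max()):
            break
    mids = 0.5 * (centroids[:-1] + centroids[1:])
    labels = np.empty(lengths.size, dtype=int)
    labels[order] = np.searchsorted(mids, sorted_lengths)
    # compact ids of any empty ranges while preserving ascending-centroid order
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    return np.array([remap[v] for v in labels], dtype=int)


def hierarchical_cluster(
    vectors: np.ndarray, threshold: float
) -> list[np.ndarray]:
    """Average-linkage clustering under the flip-invariant distance.

    Merging stops when the smallest between-cluster average distance exceeds
    ``threshold``; singletons are allowed.  Returns member-index arrays.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or len(vectors) == 0:
        raise ValidationError("need a non-empty (N, 3n) matrix")
    n = len(vectors)
    if n == 1:
        return [np.array([0])]
    d = pairwise_tract_distances(vectors)
    z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(z, t=threshold, criterion="distance")
    return [np.flatnonzero(flat == c) for c in np.unique(flat)]


def align_group_orientations(members: np.ndarray) -> np.ndarray:
    """Flip members so all sample-point sequences run the same way.

    The reference is the first member (callers pass members in ascending
    global tract index, making the choice deterministic).  A member is
    reversed only when its flipped ordering is strictly closer to the
    reference; ties keep the stored orientation.
    """
    members = np.asarray(members, dtype=float)
    if members.ndim == 1:
        members = members[None, :]
    if len(members) == 0:
        raise ValidationError("cannot align an empty group")
    ref = members[0]
    out = members.copy()
    for i in range(1, len(members)):
        f = members[i]
        fr = reverse_vector(f)
        if euclidean_distance(fr, ref) < euclidean_distance(f, ref):
            out[i] = fr
    return out


def _mean_curve(vectors: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return group_mean(align_group_orientations(vectors[idx]))


def merge_length_ranges(
    groups_by_range: list[list[TractGroup]],
    vectors: np.ndarray,
    merge_threshold: float,
) -> list[TractGroup]:
    """Merge similar groups across consecutive length ranges.

    One ascending sweep over range pairs (0,1), (1,2), ...: the
    orientation-aligned mean curves of all groups in the pair are clustered
    by average linkage at ``merge_threshold``; groups sharing a mean-curve
    cluster are merged.  A merged group that touches the higher range carries
    forward into the next pair.
    """
    ranges: list[list[TractGroup]] = [list(gs) for gs in groups_by_range]
    for r in range(len(ranges) - 1):
        pool = ranges[r] + ranges[r + 1]
        if len(pool) < 2:
            continue
        n_low = len(ranges[r])
        means = np.array([_mean_curve(vectors, g.member_indices) for g in pool])
        clusters = hierarchical_cluster(means, merge_threshold)
        new_low: list[TractGroup] = []
        new_high: list[TractGroup] = []
        for cl in clusters:
            member_groups = [pool[i] for i in cl]
            merged_idx = np.sort(np.concatenate([g.member_indices for g in member_groups]))
            touches_high = any(i >= n_low for i in cl)
            g = TractGroup(
                member_indices=merged_idx,
                length_range_id=r + 1 if touches_high else r,
            )
            (new_high if touches_high else new_low).append(g)
        ranges[r] = new_low
        ranges[r + 1] = new_high
    return [g for gs in ranges for g in gs]


def _fit_group_model(vectors: np.ndarray, idx: np.ndarray) -> GaussianGroupModel | None:
    """Fit a Gaussian model on orientation-aligned members; None for singletons."""
    if len(idx) < 2:
        return None
    return GaussianGroupModel.from_members(align_group_orientations(vectors[idx]))


def _outlier_size_threshold(sizes: np.ndarray, mass_limit: float) -> int:
    """Largest t with sum(sizes[sizes < t]) <= mass_limit * total."""
    total = sizes.sum()
    best = 1
    for t in range(1, int(sizes.max()) + 2):
        if sizes[sizes < t].sum() <= mass_limit * total:
            best = t
        else:
            break
    return best


def remove_outliers(
    groups: list[TractGroup], tract_set: TractSet, params: GroupingParams
) -> GroupingResult:
    """Flag small groups as outliers and reassign or drop their tracts.

    Tracts of outlier groups move to the non-outlier group minimizing the
    flip-invariant Mahalanobis value when that value is within the
    chi-square(3n) critical value at confidence 1 - chi2_level; otherwise
    they are removed.  Models of groups that gained members are refit.
    """
    vectors = tract_set.vectors()
    n = len(tract_set)
    sizes = np.array([g.size for g in groups])
    t = _outlier_size_threshold(sizes, params.outlier_mass_fraction)
    survivors = [g for g in groups if g.size >= t]
    outlier_groups = [g for g in groups if g.size < t]
    if not survivors:
        raise ConfigurationError("no non-outlier group survives the size threshold")

    for g in survivors:
        g.model = _fit_group_model(vectors, g.member_indices)
    modelled = [g for g in survivors if g.model is not None]
    critical = chi2.ppf(1.0 - params.chi2_level, df=vectors.shape[1])

    removed: list[int] = []
    gained: dict[int, list[int]] = {}
    for og in outlier_groups:
        for idx in og.member_indices:
            if modelled:
                dists = [tract_group_distance(vectors[idx], g.model) for g in modelled]
                best = int(np.argmin(dists))
                if dists[best] <= critical:
                    gained.setdefault(id(modelled[best]), []).append(int(idx))
                    modelled[best].member_indices = np.sort(
                        np.append(modelled[best].member_indices, idx)
                    )
                    continue
            removed.append(int(idx))

    for g in modelled:
        if id(g) in gained:
            g.model = _fit_group_model(vectors, g.member_indices)

    removed_arr = np.array(sorted(removed), dtype=int)
    result = GroupingResult(
        groups=survivors, removed_outlier_indices=removed_arr, params_used=params
    )
    _check_partition(result.groups, removed_arr, n)
    return result


def group_subject(
    tract_set: TractSet,
    params: GroupingParams | None = None,
    outlier_stage: bool = True,
) -> GroupingResult:
    """Full grouping pipeline: length partition -> per-range clustering ->
    cross-range merging -> outlier handling.  Deterministic.

    ``outlier_stage=False`` stops after merging (used e.g. when comparing
    against direct hierarchical clustering, where no outliers are removed);
    the stage is also skipped below ``MIN_TRACTS_FOR_OUTLIER_STAGE`` tracts,
    where a percent-mass rule is meaningless."""
    if params is None:
        params = GroupingParams()
    if len(tract_set) == 0:
        raise ValidationError("empty tract set")
    vectors = tract_set.vectors()
    lengths = tract_set.lengths()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k reduction on tiny inputs is expected
        range_ids = kmeans_length_partition(lengths, params.n_length_ranges, params.rng_seed)
    n_ranges = int(range_ids.max()) + 1

    groups_by_range: list[list[TractGroup]] = []
    for r in range(n_ranges):
        idx = np.flatnonzero(range_ids == r)
        if idx.size == 0:
            groups_by_range.append([])
            continue
        clusters = hierarchical_cluster(vectors[idx], params.hier_threshold)
        groups_by_range.append(
            [TractGroup(member_indices=idx[c], length_range_id=r) for c in clusters]
        )

    merged = merge_length_ranges(groups_by_range, vectors, params.merge_threshold)

    if not outlier_stage or len(tract_set) < MIN_TRACTS_FOR_OUTLIER_STAGE:
        for g in merged:
            g.model = _fit_group_model(vectors, g.member_indices)
        result = GroupingResult(
            groups=merged,
            removed_outlier_indices=np.array([], dtype=int),
            params_used=params,
        )
        _check_partition(result.groups, result.removed_outlier_indices, len(tract_set))
        return result
    return remove_outliers(merged, tract_set, params)


def grouping_consistency(
    partition_a: list[np.ndarray], partition_b: list[np.ndarray]
) -> float:
    """Percentage agreement of partition A's groups with their best match in B.

    For each group in A, the fraction of its tracts captured by the single
    best-overlapping group of B, averaged over A's groups and scaled to
    [0, 100].  Asymmetric: callers report both directions.
    """
    if not partition_a or not partition_b:
        raise ValidationError("partitions must be non-empty")
    universe_a = np.sort(np.concatenate(partition_a))
    universe_b = np.sort(np.concatenate(partition_b))
    if universe_a.shape != universe_b.shape or not np.array_equal(universe_a, universe_b):
        raise ValidationError("partitions cover different tract universes")

    b_sets = [set(map(int, g)) for g in partition_b]
    total = 0.0
    for ga in partition_a:
        sa = set(map(int, ga))
        best = max(len(sa & sb) for sb in b_sets)
        total += best / len(sa)
    return 100.0 * total / len(partition_a)
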