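"""Performance measures and the nested cross-validation parameter search.

Sensitivity and FDR compare automatically labeled tract index sets against
expert (ground-truth) sets per bundle.  The kappa statistic measures
chance-corrected voxel-overlap agreement between two binarized bundle
images, optionally restricted to voxels inside an FA >= 0.2 mask.  Nested
cross-validation selects the classifier thresholds with an inner
leave-one-subject-out loop and scores them on the outer held-out subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .atlas_classify import (
    OUTLIER,
    Atlas,
    best_match_group,
    best_match_tract,
    build_atlas,
    resolve_votes,
)
from .errors import UndefinedMetricError, ValidationError
from .grouping import GroupingParams, group_subject
from .tract_model import TractSet


def sensitivity(auto_set: set[int], manual_set: set[int]) -> float:
    """Fraction of ground-truth bundle tracts recovered: |Ba & Bm| / |Bm|."""
    manual_set = set(manual_set)
    if not manual_set:
        raise UndefinedMetricError("sensitivity undefined for empty manual set")
    return len(set(auto_set) & manual_set) / len(manual_set)


def fdr(auto_set: set[int], manual_set: set[int]) -> float:
    """Fraction of automatic labels that are wrong: 1 - |Ba & Bm| / |Ba|."""
    auto_set = set(auto_set)
    if not auto_set:
        raise UndefinedMetricError("FDR undefined for empty automatic set")
    return 1.0 - len(auto_set & set(manual_set)) / len(auto_set)


# ---------------------------------------------------------------------------
# voxel overlap

@dataclass
class VoxelMask:
    """Binary occupancy grid with half-open voxel boxes.

    Voxel (i, j, k) covers the world box
    [origin + i*voxel_size, origin + (i+1)*voxel_size).
    """

    shape: tuple[int, int, int] = (128, 128, 60)
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValidationError("mask shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel size must be positive")
        if self.occupancy is None:
            self.occupancy = np.zeros(self.shape, dtype=bool)
        else:
            self.occupancy = np.asarray(self.occupancy, dtype=bool)
            if self.occupancy.shape != tuple(self.shape):
                raise ValidationError("occupancy shape mismatch")

    def same_geometry(self, other: "VoxelMask") -> bool:
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )


def voxelize_bundle(
    tracts: TractSet | list, grid: VoxelMask | None = None
) -> VoxelMask:
    """Occupancy mask of a bundle: every voxel a tract passes through.

    Each resampled segment is supersampled at steps no longer than half the
    smallest voxel edge so traversed voxels between samples are not skipped.
    Samples falling outside the grid are ignored (count reported via warning).
    """
    if grid is None:
        grid = VoxelMask()
    shape = np.array(grid.shape)
    vs = np.array(grid.voxel_size, dtype=float)
    origin = np.array(grid.origin, dtype=float)
    step = 0.5 * vs.min()

    occupancy = np.zeros(tuple(shape), dtype=bool)
    tract_list = tracts.tracts if isinstance(tracts, TractSet) else tracts
    clipped = 0
    for t in tract_list:
        pts = t.points
        dense = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(b - a)
            n_sub = max(1, int(np.ceil(seg / step)))
            for s in range(1, n_sub + 1):
                dense.append(a + (b - a) * (s / n_sub))
        dense = np.array(dense)
        ijk = np.floor((dense - origin) / vs).astype(int)
        inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
        clipped += int((~inside).sum())
        sel = ijk[inside]
        occupancy[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    if clipped:
        warnings.warn(f"{clipped} supersampled points fell outside the grid",
                      stacklevel=2)
    return VoxelMask(
        shape=tuple(grid.shape), voxel_size=tuple(grid.voxel_size),
        origin=tuple(grid.origin), occupancy=occupancy,
    )


@dataclass(frozen=True)
class KappaTable:
    pp: int
    nn: int
    pn: int
    np_: int

    @property
    def total(self) -> int:
        return self.pp + self.nn + self.pn + self.np_


def kappa_from_table(table: KappaTable) -> float:
    """Cohen's kappa from an agreement table."""
    n = table.total
    if n <= 0:
        raise UndefinedMetricError("empty agreement table")
    po = (table.pp + table.nn) / n
    pe = ((table.pp + table.pn) / n) * ((table.pp + table.np_) / n) + (
        (table.nn + table.np_) / n
    ) * ((table.nn + table.pn) / n)
    if pe >= 1.0:
        if po >= 1.0:
            return 1.0
        raise UndefinedMetricError("chance agreement is 1 with observed disagreement")
    return (po - pe) / (1.0 - pe)


def kappa(
    mask_a: VoxelMask, mask_b: VoxelMask, fa_mask: VoxelMask | None = None
) -> float:
    """Chance-corrected voxel-overlap agreement of two binarized bundles.

    Voxels where ``fa_mask`` occupancy is False (the FA < 0.2 region) are
    excluded from the agreement table before kappa is computed.
    """
    if not mask_a.same_geometry(mask_b):
        raise ValidationError("mask geometries differ")
    sel = np.ones(mask_a.occupancy.shape, dtype=bool)
    if fa_mask is not None:
        if not mask_a.same_geometry(fa_mask):
            raise ValidationError("FA mask geometry differs")
        sel = fa_mask.occupancy
    a = mask_a.occupancy[sel]
    b = mask_b.occupancy[sel]
    table = KappaTable(
        pp=int(np.sum(a & b)),
        nn=int(np.sum(~a & ~b)),
        pn=int(np.sum(a & ~b)),
        np_=int(np.sum(~a & b)),
    )
    return kappa_from_table(table)


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class CVFoldResult:
    test_subject: int
    chosen_tau: float
    chosen_tau_v: int
    inner_score: float
    per_bundle: dict[str, tuple[float, float]]   # label -> (sensitivity, fdr)

    @property
    def mean_score(self) -> float:
        return float(
            np.mean([(s + (1.0 - f)) / 2.0 for s, f in self.per_bundle.values()])
        )


def _bundle_metrics(
    assigned: list[str], truth: list[str]
) -> dict[str, tuple[float, float]]:
    """Per-bundle (sensitivity, fdr); precision treated as 0 for empty Ba."""
    out: dict[str, tuple[float, float]] = {}
    bundles = sorted({t for t in truth if t not in (OUTLIER, "OUTLIER_TRUE")})
    for b in bundles:
        bm = {i for i, t in enumerate(truth) if t == b}
        ba = {i for i, t in enumerate(assigned) if t == b}
        sens = sensitivity(ba, bm)
        out[b] = (sens, fdr(ba, bm) if ba else 1.0)
    return out


def score_assignment(assigned: list[str], truth: list[str]) -> float:
    """Mean over bundles of (sensitivity + precision) / 2."""
    metrics = _bundle_metrics(assigned, truth)
    if not metrics:
        raise UndefinedMetricError("no ground-truth bundles to score")
    return float(np.mean([(s + (1.0 - f)) / 2.0 for s, f in metrics.values()]))


def _match_tables(
    subjects: list[tuple[TractSet, np.ndarray]],
    atlases: list[Atlas],
    mode: str,
    grouping_params: GroupingParams | None,
) -> list[dict]:
    """Precompute, per test subject, best-match distances to every atlas.

    Voting for any (tau, tau_v) grid point then reduces to a cheap tally.
    """
    tables = []
    for ts, _labels in subjects:
        vectors = ts.vectors()
        if mode == "direct":
            units = [{"members": [i]} for i in range(len(ts))]
            for u in units:
                v = vectors[u["members"][0]]
                u["best"] = {a.subject_id: best_match_tract(v, a) for a in atlases}
            tables.append({"units": units, "n": len(ts), "removed": []})
        else:
            grouping = group_subject(ts, grouping_params)
            units = []
            for g in grouping.groups:
                u = {"members": [int(i) for i in g.member_indices]}
                if g.model is None:
                    u["best"] = None
                else:
                    u["best"] = {
                        a.subject_id: best_match_group(g.model, a) for a in atlases
                    }
                units.append(u)
            tables.append(
                {
                    "units": units,
                    "n": len(ts),
                    "removed": [int(i) for i in grouping.removed_outlier_indices],
                }
            )
    return tables


def _labels_from_table(
    table: dict, atlas_ids: list[str], tau: float, tau_v: int
) -> list[str]:
    out = [OUTLIER] * table["n"]
    for u in table["units"]:
        if u["best"] is None:
            continue
        best = {sid: u["best"][sid] for sid in atlas_ids}
        label = resolve_votes(best, tau, tau_v).label
        for i in u["members"]:
            out[i] = label
    return out


def nested_cv_select(
    subjects: list[tuple[TractSet, np.ndarray]],
    tau_grid: list[float],
    tau_v_grid: list[int],
    mode: str = "group",
    grouping_params: GroupingParams | None = None,
) -> list[CVFoldResult]:
    """Leave-one-subject-out nested cross-validation over threshold grids.

    ``tau_grid`` holds SKLD thresholds in group mode and Mahalanobis
    thresholds in direct mode.  The inner loop leaves out each remaining
    subject in turn, scores every grid point by the mean per-bundle
    (sensitivity + precision) / 2, and the inner-best configuration (ties:
    smallest tau, then smallest tau_v) labels the outer held-out subject.
    """
    if len(subjects) < 3:
        raise ValidationError("nested CV needs at least 3 subjects")
    if mode not in ("group", "direct"):
        raise ValidationError(f"unknown mode {mode!r}")
    n_sub = len(subjects)

    # one atlas and one match table per subject, built once
    atlases = []
    for s, (ts, labels) in enumerate(subjects):
        grouping = group_subject(ts, grouping_params)
        atlases.append(build_atlas(ts, labels, grouping, subject_id=f"s{s}"))
    tables = _match_tables(subjects, atlases, mode, grouping_params)

    results: list[CVFoldResult] = []
    for outer in range(n_sub):
        train = [s for s in range(n_sub) if s != outer]
        best_cfg = None
        for tau in sorted(tau_grid):
            for tau_v in sorted(tau_v_grid):
                scores = []
                for inner in train:
                    inner_atlas_ids = [f"s{s}" for s in train if s != inner]
                    assigned = _labels_from_table(
                        tables[inner], inner_atlas_ids, tau, tau_v
                    )
                    truth = [str(l) for l in subjects[inner][1]]
                    scores.append(score_assignment(assigned, truth))
                mean_score = float(np.mean(scores))
                if best_cfg is None or mean_score > best_cfg[0] + 1e-12:
                    best_cfg = (mean_score, tau, tau_v)
        inner_score, tau, tau_v = best_cfg
        outer_atlas_ids = [f"s{s}" for s in train]
        assigned = _labels_from_table(tables[outer], outer_atlas_ids, tau, tau_v)
        truth = [str(l) for l in subjects[outer][1]]
        results.append(
            CVFoldResult(
                test_subject=outer,
                chosen_tau=tau,
                chosen_tau_v=tau_v,
                inner_score=inner_score,
                per_bundle=_bundle_metrics(assigned, truth),
            )
        )
    return results
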