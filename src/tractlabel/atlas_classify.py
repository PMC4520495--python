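"""Per-subject atlases and the multi-atlas voting classifier.

An atlas is one example subject's expert-labeled tract groups, each
summarized as a Gaussian model in a common reference space, plus the affine
that brought the subject there.  To label a query group, every atlas finds
its own most similar group by symmetric KL divergence; if that best SKLD is
within the qualification threshold tau_d the atlas casts one vote for the
bundle containing it.  The bundle with the most votes wins when its count
reaches the vote threshold tau_v, otherwise the query is declared OUTLIER.
Direct per-tract labeling works identically with the flip-invariant
Mahalanobis value and threshold tau_m in place of SKLD/tau_d.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bundle_stats import (
    GaussianGroupModel,
    reverse_model,
    skld,
    skld_flip,
    tract_group_distance,
)
from .errors import ValidationError
from .grouping import (
    GroupingParams,
    GroupingResult,
    align_group_orientations,
    group_subject,
)
from .tract_model import Tract, TractSet

OUTLIER = "OUTLIER"

#: Bundle vocabulary: the seven major association/projection bundles,
#: one label per hemisphere.
DEFAULT_BUNDLES = ("ATR", "CST", "CG", "IFO", "ILF", "SLF", "UNC")
DEFAULT_VOCABULARY = tuple(
    f"{b}_{h}" for b in DEFAULT_BUNDLES for h in ("L", "R")
) + DEFAULT_BUNDLES

ATLAS_FORMAT_VERSION = 1

# A group's label must be carried by at least this fraction of its members.
LABEL_AGREEMENT_MIN = 0.9


@dataclass
class Atlas:
    """One example subject's labeled Gaussian groups in reference space."""

    subject_id: str
    labeled_groups: list[tuple[GaussianGroupModel, str]]
    affine_to_reference: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = "reference"
    n_samples: int = 32
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        a = np.asarray(self.affine_to_reference, dtype=float)
        if a.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(a[:3, :3])) < 1e-12:
            raise ValidationError("atlas affine is singular")
        self.affine_to_reference = a

    @property
    def labels(self) -> list[str]:
        return sorted({lbl for _, lbl in self.labeled_groups})


@dataclass
class ClassifierConfig:
    """Thresholds of the voting classifier.

    ``tau_v=None`` resolves at vote time to the majority of the atlas count.
    Defaults for tau_d and tau_m sit mid-grid of the values appropriate for
    96-dimensional whole-brain data; synthetic-scale runs should calibrate
    them (see :func:`calibrate_thresholds`).
    """

    tau_d: float = 50_000.0     # SKLD qualification threshold (group mode)
    tau_m: float = 300.0        # Mahalanobis threshold (direct mode)
    tau_v: int | None = None    # minimum winning vote count
    mode: str = "group"         # "group" | "direct"

    def __post_init__(self) -> None:
        if self.tau_d <= 0 or self.tau_m <= 0:
            raise ValidationError("distance thresholds must be positive")
        if self.tau_v is not None and self.tau_v < 1:
            raise ValidationError("tau_v must be >= 1")
        if self.mode not in ("group", "direct"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    def resolve_tau_v(self, n_atlases: int) -> int:
        if self.tau_v is not None:
            return self.tau_v
        return n_atlases // 2 + 1


@dataclass
class LabelAssignment:
    """Outcome of voting for one unit (a group or a single tract)."""

    unit_id: int
    label: str
    votes: dict[str, int]
    qualified_voters: int
    best_skld_per_atlas: dict[str, float]


def apply_affine(tract_set: TractSet, affine: np.ndarray) -> TractSet:
    """Map every raw and resampled point homogeneously; recompute lengths."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine is singular")
    lin, trans = affine[:3, :3], affine[:3, 3]

    new_tracts = []
    for t in tract_set.tracts:
        raw = t.raw_points @ lin.T + trans
        pts = t.points @ lin.T + trans
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        new_tracts.append(
            Tract(raw_points=raw, vector=pts.reshape(-1), n_samples=t.n_samples,
                  length_mm=length)
        )
    new_tag = "reference" if tract_set.space_tag == "subject" else tract_set.space_tag
    return TractSet(tracts=new_tracts, space_tag=new_tag)


def build_atlas(
    tract_set: TractSet,
    labels: dict[int, str] | np.ndarray,
    grouping: GroupingResult,
    subject_id: str,
    affine: np.ndarray | None = None,
) -> Atlas:
    """Turn a grouped, expert-labeled subject into an atlas.

    The subject's tracts are first mapped to the reference space by
    ``affine`` (identity when omitted).  Each non-outlier group takes the
    majority label of its members when at least 90% agree; groups failing
    the agreement bar, labeled "unlabeled", or too small to model are
    excluded with a warning.
    """
    if affine is None:
        affine = np.eye(4)
    ref_set = apply_affine(tract_set, affine)
    vectors = ref_set.vectors()

    if isinstance(labels, np.ndarray):
        labels = {i: str(l) for i, l in enumerate(labels)}

    labeled_groups: list[tuple[GaussianGroupModel, str]] = []
    for g in grouping.groups:
        member_labels = [labels.get(int(i)) for i in g.member_indices]
        if any(l is None for l in member_labels):
            raise ValidationError("atlas subject has unlabeled member tracts")
        values, counts = np.unique(member_labels, return_counts=True)
        top = int(np.argmax(counts))
        if counts[top] / len(member_labels) < LABEL_AGREEMENT_MIN:
            warnings.warn(
                f"group of size {g.size} excluded: majority label below 90% agreement",
                stacklevel=2,
            )
            continue
        label = str(values[top])
        if label in ("unlabeled", OUTLIER):
            continue
        if g.size < 2:
            warnings.warn("singleton group excluded from atlas", stacklevel=2)
            continue
        model = GaussianGroupModel.from_members(
            align_group_orientations(vectors[g.member_indices])
        )
        labeled_groups.append((model, label))

    if not labeled_groups:
        raise ValidationError(f"no labeled groups for atlas subject {subject_id}")
    return Atlas(
        subject_id=subject_id,
        labeled_groups=labeled_groups,
        affine_to_reference=np.asarray(affine, dtype=float),
        n_samples=ref_set.n_samples,
    )


# ---------------------------------------------------------------------------
# voting core

def best_match_group(query: GaussianGroupModel, atlas: Atlas) -> tuple[float, str]:
    """(min flip-invariant SKLD, bundle label) over the atlas's groups.

    The query's reversal is factored once and reused across the atlas.
    """
    rev = reverse_model(query)
    dists = [
        min(skld(query, m), skld(rev, m)) for m, _ in atlas.labeled_groups
    ]
    best = int(np.argmin(dists))
    return float(dists[best]), atlas.labeled_groups[best][1]


def best_match_tract(query: np.ndarray, atlas: Atlas) -> tuple[float, str]:
    """(min flip-invariant Mahalanobis, bundle label) over the atlas's groups."""
    dists = [tract_group_distance(query, m) for m, _ in atlas.labeled_groups]
    best = int(np.argmin(dists))
    return float(dists[best]), atlas.labeled_groups[best][1]


def resolve_votes(
    per_atlas_best: dict[str, tuple[float, str]],
    tau_dist: float,
    tau_v: int,
    unit_id: int = 0,
) -> LabelAssignment:
    """Tally qualified votes and resolve the winning label.

    An atlas qualifies when its best distance is <= tau_dist.  The label
    with the most votes wins if its count >= tau_v.  Ties between labels
    with equal maximal votes go to the label with the smallest best
    distance among its voting atlases; an exact distance tie falls back to
    OUTLIER.  The rule depends only on the set of atlases, not their order.
    """
    votes: dict[str, int] = {}
    best_dist_per_label: dict[str, float] = {}
    qualified = 0
    for _, (dist, label) in per_atlas_best.items():
        if dist <= tau_dist:
            qualified += 1
            votes[label] = votes.get(label, 0) + 1
            best_dist_per_label[label] = min(
                best_dist_per_label.get(label, np.inf), dist
            )

    label = OUTLIER
    if votes:
        top = max(votes.values())
        if top >= tau_v:
            tied = sorted(l for l, c in votes.items() if c == top)
            if len(tied) == 1:
                label = tied[0]
            else:
                dists = [best_dist_per_label[l] for l in tied]
                order = np.argsort(dists)
                if dists[order[0]] < dists[order[1]]:
                    label = tied[order[0]]
                # exact distance tie: stay OUTLIER (conservative)
    return LabelAssignment(
        unit_id=unit_id,
        label=label,
        votes=votes,
        qualified_voters=qualified,
        best_skld_per_atlas={sid: d for sid, (d, _) in per_atlas_best.items()},
    )


def vote_label_group(
    query: GaussianGroupModel, atlases: list[Atlas], config: ClassifierConfig,
    unit_id: int = 0,
) -> LabelAssignment:
    """Label one query group by SKLD voting across atlases."""
    if not atlases:
        raise ValidationError("need at least one atlas")
    best = {a.subject_id: best_match_group(query, a) for a in atlases}
    return resolve_votes(best, config.tau_d, config.resolve_tau_v(len(atlases)), unit_id)


def vote_label_tract(
    query: np.ndarray, atlases: list[Atlas], config: ClassifierConfig,
    unit_id: int = 0,
) -> LabelAssignment:
    """Label one tract directly by flip-invariant Mahalanobis voting."""
    if not atlases:
        raise ValidationError("need at least one atlas")
    best = {a.subject_id: best_match_tract(query, a) for a in atlases}
    return resolve_votes(best, config.tau_m, config.resolve_tau_v(len(atlases)), unit_id)


def classify_subject(
    tract_set: TractSet,
    atlases: list[Atlas],
    config: ClassifierConfig | None = None,
    grouping_params: GroupingParams | None = None,
    affine: np.ndarray | None = None,
) -> list[LabelAssignment]:
    """Label every tract of a test subject.

    Group mode: the subject is grouped by shape, each group is voted on and
    its label inherited by every member tract; tracts removed as grouping
    outliers (and groups too small to model) are labeled OUTLIER.  Direct
    mode: each tract is voted on individually, without grouping.
    """
    if config is None:
        config = ClassifierConfig()
    if not atlases:
        raise ValidationError("need at least one atlas")
    if affine is not None:
        tract_set = apply_affine(tract_set, affine)
    vectors = tract_set.vectors()
    n = len(tract_set)

    if config.mode == "direct":
        return [
            vote_label_tract(vectors[i], atlases, config, unit_id=i) for i in range(n)
        ]

    grouping = group_subject(tract_set, grouping_params)
    assignments: list[LabelAssignment | None] = [None] * n
    for g in grouping.groups:
        if g.model is None:
            ga = LabelAssignment(
                unit_id=-1, label=OUTLIER, votes={}, qualified_voters=0,
                best_skld_per_atlas={},
            )
        else:
            ga = vote_label_group(g.model, atlases, config)
        for i in g.member_indices:
            assignments[int(i)] = LabelAssignment(
                unit_id=int(i), label=ga.label, votes=dict(ga.votes),
                qualified_voters=ga.qualified_voters,
                best_skld_per_atlas=dict(ga.best_skld_per_atlas),
            )
    for i in grouping.removed_outlier_indices:
        assignments[int(i)] = LabelAssignment(
            unit_id=int(i), label=OUTLIER, votes={}, qualified_voters=0,
            best_skld_per_atlas={},
        )
    assert all(a is not None for a in assignments)
    return assignments  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# threshold calibration (for data whose distance magnitudes differ from
# whole-brain 96-dimensional tractograms)

def calibrate_thresholds(
    atlases: list[Atlas],
    calib_set: TractSet,
    calib_labels: dict[int, str] | np.ndarray,
    quantile: float = 0.95,
    headroom: float = 2.0,
) -> tuple[float, float]:
    """Set tau_d / tau_m from within-bundle distances on a held-out subject.

    tau_d starts from the ``quantile`` of flip-invariant SKLDs between the
    calibration subject's per-bundle Gaussian models and the best
    same-bundle group of each atlas; tau_m from the same quantile of each
    calibration tract's best flip-invariant Mahalanobis value against
    same-bundle atlas groups.  Both are scaled by ``headroom``: a threshold
    at the bare quantile sits inside the within-bundle distance
    distribution, so with majority voting roughly (1 - quantile) of
    legitimate queries would fail qualification by construction.  Within-
    and cross-bundle distances are separated by orders of magnitude, so any
    modest factor places the threshold in the gap.
    """
    if isinstance(calib_labels, np.ndarray):
        calib_labels = {i: str(l) for i, l in enumerate(calib_labels)}
    vectors = calib_set.vectors()
    by_label: dict[str, list[int]] = {}
    for i, lbl in calib_labels.items():
        if lbl in ("unlabeled", OUTLIER, "OUTLIER_TRUE"):
            continue
        by_label.setdefault(lbl, []).append(int(i))

    skld_vals: list[float] = []
    maha_vals: list[float] = []
    for lbl, idx in by_label.items():
        if len(idx) < 2:
            continue
        model = GaussianGroupModel.from_members(
            align_group_orientations(vectors[np.array(idx)])
        )
        for atlas in atlases:
            same = [m for m, l in atlas.labeled_groups if l == lbl]
            if not same:
                continue
            skld_vals.append(min(skld_flip(model, m) for m in same))
            for i in idx:
                maha_vals.append(
                    min(tract_group_distance(vectors[i], m) for m in same)
                )
    if not skld_vals or not maha_vals:
        raise ValidationError("no shared bundle labels between atlases and calibration set")
    return (
        headroom * float(np.quantile(skld_vals, quantile)),
        headroom * float(np.quantile(maha_vals, quantile)),
    )


def split_by_hemisphere(tract_set: TractSet) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (left, right) by the sign of each tract's mean x (RAS:
    negative x = left).  A convention helper; callers own hemisphere logic."""
    mean_x = np.array([t.points[:, 0].mean() for t in tract_set.tracts])
    return np.flatnonzero(mean_x < 0), np.flatnonzero(mean_x >= 0)


# ---------------------------------------------------------------------------
# atlas persistence: directory with manifest.json + groups.npz

def save_atlas(atlas: Atlas, path: str | Path) -> None:
    """Write an atlas directory (versioned manifest + per-group arrays)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels = [lbl for _, lbl in atlas.labeled_groups]
    manifest = {
        "format_version": ATLAS_FORMAT_VERSION,
        "subject_id": atlas.subject_id,
        "space_tag": atlas.space_tag,
        "n_samples": atlas.n_samples,
        "vocabulary": list(atlas.vocabulary),
        "affine_to_reference": [float(v) for v in atlas.affine_to_reference.reshape(-1)],
        "group_labels": labels,
        "n_groups": len(labels),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(
        path / "groups.npz",
        means=np.array([m.mean for m, _ in atlas.labeled_groups]),
        covs=np.array([m.cov for m, _ in atlas.labeled_groups]),
        n_members=np.array([m.n_members for m, _ in atlas.labeled_groups]),
    )


def load_atlas(path: str | Path) -> Atlas:
    """Read an atlas directory written by :func:`save_atlas` (bit-exact)."""
    from .errors import FormatError

    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable atlas manifest at {path}: {exc}") from exc
    if manifest.get("format_version") != ATLAS_FORMAT_VERSION:
        raise FormatError(
            f"unsupported atlas format_version {manifest.get('format_version')}"
        )
    with np.load(path / "groups.npz") as arrays:
        means, covs, n_members = arrays["means"], arrays["covs"], arrays["n_members"]
    labels = manifest["group_labels"]
    if not (len(labels) == len(means) == len(covs)):
        raise FormatError("atlas manifest and arrays disagree on group count")
    groups = [
        (GaussianGroupModel.from_moments(means[i], covs[i], int(n_members[i])), labels[i])
        for i in range(len(labels))
    ]
    return Atlas(
        subject_id=manifest["subject_id"],
        labeled_groups=groups,
        affine_to_reference=np.array(manifest["affine_to_reference"]).reshape(4, 4),
        space_tag=manifest["space_tag"],
        n_samples=int(manifest["n_samples"]),
        vocabulary=tuple(manifest["vocabulary"]),
    )
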