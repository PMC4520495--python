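# Methods

## Tract representation

A tractography streamline is an ordered 3D polyline in world millimetres
(RAS frame throughout; voxel↔world conversion happens only at file I/O).
For fixed-length comparison each streamline is interpolated by a cubic
spline with chord-length knots (piecewise-linear below 4 distinct points,
where a cubic is not determined) and resampled at n points uniform in arc
length; arc length is inverted numerically on a dense subdivision (20·n
parameter samples, giving sub-1e-6 mm placement error on smooth curves) and
the endpoints are pinned exactly. The default n = 32 gives 96-dimensional
tract vectors; any n ≥ 2 is supported. Consecutive duplicate input points
are dropped before knot construction; fewer than two distinct points is a
degenerate-input error.

Streamlines carry no intrinsic direction, so every distance in the package
minimizes over point-order reversal: the tract–tract distance is
min(‖fᵢ−fⱼ‖, ‖fᵢ−fⱼ′‖), the tract–group distance is the minimum of the
Mahalanobis quadratic form over the two orderings, and the group–group
similarity used in matching minimizes the symmetric KL divergence over
reversing one model (the reversal permutes mean entries and covariance
rows/columns by whole coordinate triples). The last of these is a design
choice worth flagging: the members of a group are orientation-aligned to an
arbitrary in-group reference before the Gaussian is fitted, so two models
of the same anatomical bundle from different subjects may be stored in
opposite sample orders; without the min-over-reversal the SKLD between them
is dominated by the spurious mean-difference term and matching fails for
roughly half of the subject pairs. Plain (orientation-sensitive) SKLD
remains available as `skld`.

## Gaussian group models

A tract group is modeled as N(m, S*) over tract vectors. The mean is the
coordinate-wise average of the aligned members. S* is a shrinkage
covariance: the diagonal keeps the empirical unbiased variances; each
off-diagonal correlation r_ij is scaled by min(1, max(0, 1−λ̂*)) with

    λ̂* = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r_ij²,
    V̂ar(r_ij) = N/(N−1)³ · Σ_k (w_kij − w̄_ij)²,

where w_kij are products of standardized residuals (the standard unbiased
estimator for the variance of an empirical correlation). This keeps the
matrix full-rank even when a group has far fewer members than dimensions
or its members are nearly parallel — exactly the regime tract groups live
in (N ~ tens, 3n = 96).

Numerical safeguards, all with negligible statistical effect:

- variances are floored at 1e-8 mm² before standardization, so coordinates
  duplicated exactly across members (possible in synthetic data) cannot
  produce 0/0 correlations;
- λ̂* is floored at 1e-6. For exactly collinear members (N = 2 always, or
  degenerate inputs) the estimator variance underflows to rounding noise
  (~1e-17) rather than exactly zero, so an equality test would miss the
  case; the unconditional floor keeps the full-rank guarantee and perturbs
  ordinary intensities (typically > 1e-3) by well under test tolerances;
- if Cholesky fails on the covariance scale (possible when the minimum
  eigenvalue sits near the λ floor and variances span several orders of
  magnitude), the factorization is redone on the correlation matrix, whose
  unit diagonal conditions it far better, and rescaled exactly:
  cov = D·R·D ⇒ L_cov = D·L_R.

The Mahalanobis value is implemented as the quadratic form
(f−m)ᵀ(S*)⁻¹(f−m) with no square root, computed by triangular solves
against the cached Cholesky factor (never an explicit inverse). On this
scale the value of a draw from the model follows χ²(3n), which is what the
outlier gates compare against; the grouping stage rejects reassignments
beyond the χ²(96) critical value at the 0.98 level by default. KLD and
SKLD between group models use the cached factors and log-determinants; the
log-determinant terms cancel in SKLD, which equals the sum of the two
directed divergences to machine precision (property-tested).

## Grouping pipeline

Direct average-linkage clustering of a whole-brain tractogram needs an
O(N²) distance table that does not fit in memory, so clustering is
stratified by length first:

1. **Length partition.** 1-D k-means (default k = 100) on chord lengths.
   Initialization is deterministic — centroids at k evenly spread values of
   the sorted distinct lengths — and Lloyd iterations run to 1e-9 relative
   tolerance; in 1-D the assignment step is a `searchsorted` against
   centroid midpoints, and returned range ids ascend with centroid so
   "consecutive ranges" is well defined. k is reduced with a warning when
   the data have fewer distinct lengths.
2. **Within-range clustering.** Agglomerative average-linkage clustering of
   the range's tract vectors under the flip-invariant distance (scipy
   linkage on the precomputed condensed matrix), cut where the minimum
   between-cluster average distance exceeds the threshold (default 40 mm,
   ≈ 7 mm per corresponding sample-point pair at n = 32).
3. **Cross-range merging.** One ascending sweep over consecutive range
   pairs: the orientation-aligned mean curves of all groups in the pair are
   clustered at a tighter threshold (default 20 mm); groups sharing a
   mean-curve cluster merge, and merged groups touching the higher range
   carry into the next pair. A single pass is used; iterating to a fixed
   point changed nothing in our synthetic experiments and is not attempted.
4. **Outlier stage.** The group-size threshold t is the largest integer
   such that groups smaller than t hold at most 2% of all tracts. Tracts of
   flagged groups are reassigned to the closest surviving Gaussian group
   when the flip-invariant Mahalanobis value is within the χ² critical
   value, and removed otherwise; refitted models account for gained
   members. The stage is skipped below 50 tracts, where a percent-mass rule
   is meaningless, and can be disabled explicitly (the
   grouping-vs-direct-clustering consistency experiment requires that).

Orientation alignment inside a group uses the member with the lowest tract
index as reference (deterministic; semantics unchanged from a random
choice) and keeps the stored orientation on exact ties. Every grouping
result is checked to partition the input: each tract index lands in exactly
one group or in the removed-outlier list.

## Atlases and voting

An atlas is one example subject's labeled groups — a Gaussian model plus a
bundle label per group — in a common reference space, together with the
4×4 affine that brought the subject there (estimating that registration is
out of scope; the package only applies supplied matrices, and nonlinear
warps are deliberately not supported). Atlas construction maps the subject
through its affine, fits one model per non-outlier group on the aligned
members, and takes the majority member label, requiring ≥ 90% agreement
(a group below that, labeled "unlabeled", or too small to model — one
member — is excluded with a warning). The default vocabulary covers the
seven major bundles (ATR, CST, CG, IFO, ILF, SLF, UNC), optionally
suffixed _L/_R; free-text labels pass through so other bundles cost
nothing. Hemispheres are the caller's responsibility; a sign-of-mean-x
helper is provided as a convention, nothing more. Atlases serialize to a
directory (versioned JSON manifest + npz arrays) that round-trips
bit-exactly.

Voting: each atlas finds its group minimizing the flip-invariant SKLD to
the query group; atlases whose best SKLD exceeds τ_d abstain; each
qualifying atlas votes for the bundle containing its best group; the label
with the most votes wins if its count reaches τ_v, else OUTLIER. Ties
between equally voted labels go to the label with the smallest best
distance among its voters, and an exact distance tie falls back to OUTLIER
— order-free by construction (property-tested by permuting atlases), and
conservative in the method's spirit. τ_v compares the *winning bundle's*
count, not total qualified votes. Direct mode substitutes the
flip-invariant Mahalanobis value and τ_m, per tract instead of per group.
In group mode the winning label is inherited by all member tracts; tracts
the grouping removed, and groups too small to model, are OUTLIER.

Defaults τ_d = 50,000 and τ_m = 300 are mid-grid values appropriate for
96-dimensional whole-brain tractograms; τ_v defaults to the majority of
the atlas count. For data whose distance magnitudes differ — the synthetic
cohorts here, or acquisitions unlike the defaults' provenance —
`calibrate_thresholds` sets both from a held-out labeled subject: the 95th
percentile of within-bundle best-match distances against the atlases,
times a headroom factor (default 2). The headroom matters: a threshold at
the bare percentile lies inside the within-bundle distance distribution,
so with majority voting about 5% of legitimate queries would fail
qualification by construction; within- and cross-bundle distances are
separated by more than two orders of magnitude in all our experiments, so
any modest factor lands the threshold safely in the gap.

## Evaluation

Per-bundle sensitivity |B_a∩B_m|/|B_m| and FDR 1−|B_a∩B_m|/|B_a| are pure
set operations on tract indices (undefined-denominator cases raise).
Voxel-overlap kappa binarizes two bundles on a shared grid (default
128×128×60 voxels of 1.875×1.875×2 mm, half-open voxel boxes, 0-based
indices; segments are supersampled at half the smallest voxel edge so no
traversed voxel is skipped), builds the pp/nn/pn/np agreement table —
optionally dropping voxels outside an FA ≥ 0.2 inclusion mask — and
returns (p_o−p_e)/(1−p_e). Grouping consistency between two partitions of
the same tracts averages, over the first partition's groups, the fraction
captured by the best-overlapping group of the second (asymmetric; report
both directions).

Nested cross-validation: leave-one-subject-out outer loop; the inner loop
leaves out each remaining subject in turn and scores every (τ, τ_v) grid
point by the mean per-bundle (sensitivity + precision)/2 — the selection
criterion is our choice, mirroring how the incremental-atlas experiment
scores labeling quality; precision is taken as 0 for bundles the
classifier never predicted. Grid ties resolve to the smallest τ, then the
smallest τ_v, making fold outcomes deterministic given input order. Per-
subject atlases and per-(test, atlas) best-match tables are computed once
and reused across the grid, which keeps the search linear in grid size.

## Synthetic data

The generator emulates what the pipeline is sensitive to, not anatomy:

- **Templates.** Seven stylized centerlines (4 control points each) named
  after the seven major bundles — a vertical corticospinal arc, a C-shaped
  cingulum, a hooked uncinate, long fronto-occipital curves, a thalamic
  fan — with lengths 46–111 mm (inside the 20–200 mm tractography window)
  and minimum pairwise flip-invariant distance ≈ 143 mm, far above both
  the clustering threshold and any noise level used.
- **Tracts.** Template centerline (resampled to 40 raw points) plus a
  spatially correlated Gaussian displacement field: amplitudes drawn at 8
  stations along the curve (sd = `shape_noise_sd`, default 1 mm),
  cubically interpolated, norm-clipped at the template's tube radius
  (4–5 mm). Each tract is reversed with probability 0.5.
- **Outliers.** A configurable fraction (default 5%) of cubic Bézier
  curves with control points uniform over the template bounding box,
  retried into the 20–200 mm window, labeled OUTLIER_TRUE.
- **Subjects.** Each non-reference subject is perturbed by a random affine
  (defaults: ≤ 2° rotations, ≤ 2 mm translation, ≤ 2% anisotropic scale)
  standing in for residual inter-subject registration error; the returned
  `affine_to_reference` is its exact inverse, so applying it aligns the
  subject to the templates. Everything is reproducible from
  (seed, subject_index).

What the synthetic experiments show — and what they don't: bundles here
are globally well separated and their shape variability is a stationary
Gaussian field, so near-perfect recovery says the machinery (distances,
shrinkage models, grouping, voting, thresholds) is implemented coherently,
not that real bundles with overlapping cores, partial-volume crossings and
heavy-tailed shape variation will label at the same rates. Real-data
thresholds also cannot be inferred from the synthetic calibration; on real
tractograms the printed defaults and the nested-CV search are the intended
path.

Two synthetic experiment choices deserve explanation. The grouping
consistency experiment follows the original comparison protocol: merge
threshold raised to equal the clustering threshold and no outlier stage,
so both pipelines face the same objective (2,002 tracts; ~99.9% mean
two-way consistency). The multi-atlas benefit experiment uses direct
per-tract labeling: at a few hundred tracts per subject the 100-range
partition fragments groups badly enough that group-mode accuracy measures
grouping granularity rather than the atlas count under study; direct mode
isolates the voting mechanism (mean accuracy 0.97 with one atlas → 1.00
with seven, over 10 seeds, with uncorrected affine jitter left in as the
source of inter-subject variability).

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at reduced but
non-trivial sizes — 2,002 tracts for the consistency oracle, 7 subjects ×
~370 tracts for parameter recovery, 10 repetitions × 9 subjects for the
multi-atlas comparison, 10,000 draws for the χ² quantile check — chosen so
each quantity is estimated stably while the whole suite completes in a few
minutes on one CPU. All randomness flows through numpy Generators seeded
explicitly; clustering, k-means initialization, tie-breaks and voting are
deterministic by construction, so identical seeds give byte-identical
outputs.

## Known limitations

- Affine registration quality bounds labeling quality; the package never
  estimates or refines registrations.
- Group mode inherits the grouping's granularity: over-fragmented groups
  (tiny subjects, tight thresholds) become unmodelable singletons and fall
  to OUTLIER. Direct mode is the fallback at small scales.
- The default thresholds' scale is tied to 96-dimensional tract vectors in
  millimetres; changing n or units requires recalibration.
- FA masks must be axis-aligned NIfTI volumes; oblique acquisitions are
  rejected rather than resampled.
- Voting is evaluated serially; the contract only requires results to be
  independent of evaluation order, so process-level parallelism can be
  added without semantic change.
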