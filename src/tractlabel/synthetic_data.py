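"""Synthetic multi-subject "tractography" with known bundle labels.

The generator emulates the geometry that matters to the labeling pipeline:
bundles of smooth 3D curves scattered around a stylized centerline by a
spatially correlated Gaussian displacement field, random point-order flips,
a configurable fraction of unrelated outlier curves, and a small per-subject
affine perturbation standing in for residual inter-subject registration
error.  It makes no claim of anatomical realism and simulates no diffusion
signal; bundle names follow the seven major bundles by convention only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .tract_model import TractSet, resample_polyline, resample_tract

OUTLIER_TRUE = "OUTLIER_TRUE"

#: points per generated raw polyline
RAW_POINTS = 40

#: control points of the per-tract displacement field
FIELD_CONTROLS = 8


@dataclass(frozen=True)
class BundleTemplate:
    """Stylized centerline of one synthetic bundle."""

    name: str
    centerline: np.ndarray     # (m >= 4, 3) control points, mm
    tube_radius: float         # mm, cap on displacement magnitude

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 4 or cl.shape[1] != 3:
            raise ValidationError("centerline needs >= 4 control points")
        if self.tube_radius <= 0:
            raise ValidationError("tube_radius must be positive")
        object.__setattr__(self, "centerline", cl)

    @property
    def length_mm(self) -> float:
        dense = resample_polyline(self.centerline, 200)
        return float(np.linalg.norm(np.diff(dense, axis=0), axis=1).sum())


@dataclass
class AffineJitter:
    """Bounds of the per-subject affine perturbation around identity."""

    max_rotation_deg: float = 2.0
    max_translation_mm: float = 2.0
    max_scale_fraction: float = 0.02

    def __post_init__(self) -> None:
        if min(self.max_rotation_deg, self.max_translation_mm,
               self.max_scale_fraction) < 0:
            raise ValidationError("jitter bounds must be non-negative")


@dataclass
class SyntheticCohortSpec:
    """Study conditions of a synthetic cohort."""

    templates: list[BundleTemplate] = field(default_factory=lambda: default_templates())
    n_subjects: int = 6
    tracts_per_bundle: int = 50
    shape_noise_sd: float = 1.0                   # mm
    subject_affine_jitter: AffineJitter = field(default_factory=AffineJitter)
    outlier_fraction: float = 0.05
    flip_probability: float = 0.5
    n_samples: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_noise_sd < 0:
            raise ValidationError("shape_noise_sd must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise ValidationError("outlier_fraction must be in [0, 1)")
        if not (0 <= self.flip_probability <= 1):
            raise ValidationError("flip_probability must be in [0, 1]")
        if self.n_subjects < 1 or self.tracts_per_bundle < 1:
            raise ValidationError("need >= 1 subject and >= 1 tract per bundle")


@dataclass
class SyntheticSubject:
    """One generated subject, in its own (possibly jittered) space."""

    tract_set: TractSet
    labels: np.ndarray                 # per-tract bundle name or OUTLIER_TRUE
    affine_to_reference: np.ndarray    # 4x4; identity for the reference subject
    is_reference: bool = False


def default_templates() -> list[BundleTemplate]:
    """Seven stylized bundle centerlines, one per major bundle name.

    Geometries echo the field's shorthand (vertical corticospinal arc,
    C-shaped cingulum, hooked uncinate, long fronto-occipital curves, a
    thalamic fan) inside a right-hemisphere-sized box; centerline lengths
    sit inside the 20-200 mm tractography window and pairwise separations
    far exceed the default 1 mm shape noise.
    """
    defs = [
        ("CST", [(25, -20, -45), (26, -22, -12), (27, -25, 14), (28, -18, 42)], 5.0),
        ("CG", [(8, 38, 6), (8, 16, 30), (8, -12, 33), (8, -42, 8)], 4.0),
        ("UNC", [(34, 4, -32), (39, 14, -26), (37, 28, -24), (30, 40, -13)], 4.0),
        ("SLF", [(30, 42, 24), (37, 12, 32), (38, -18, 31), (34, -47, 20)], 5.0),
        ("ILF", [(41, -61, -4), (44, -36, -12), (45, -12, -19), (42, 11, -26)], 5.0),
        ("IFO", [(27, 46, 1), (34, 12, -6), (36, -22, -9), (31, -61, 3)], 5.0),
        ("ATR", [(11, -16, 7), (13, 4, 11), (17, 25, 13), (23, 45, 16)], 5.0),
    ]
    return [
        BundleTemplate(name=n, centerline=np.array(c, dtype=float), tube_radius=r)
        for n, c, r in defs
    ]


def _smooth_displacement(rng: np.random.Generator, n_points: int, sd: float,
                         radius: float) -> np.ndarray:
    """Spatially correlated Gaussian field: amplitudes at FIELD_CONTROLS
    equally spaced stations along the curve, cubically interpolated."""
    if sd == 0:
        return np.zeros((n_points, 3))
    knots = np.linspace(0.0, 1.0, FIELD_CONTROLS)
    amps = rng.normal(0.0, sd, size=(FIELD_CONTROLS, 3))
    spline = CubicSpline(knots, amps, axis=0)
    disp = spline(np.linspace(0.0, 1.0, n_points))
    norms = np.linalg.norm(disp, axis=1)
    over = norms > radius
    if np.any(over):
        disp[over] *= (radius / norms[over])[:, None]
    return disp


def _random_bezier(rng: np.random.Generator, box_lo: np.ndarray,
                   box_hi: np.ndarray) -> np.ndarray:
    """A cubic Bezier curve with control points uniform in the template box,
    retried until its length lands inside the 20-200 mm window."""
    t = np.linspace(0.0, 1.0, RAW_POINTS)
    bernstein = np.stack(
        [(1 - t) ** 3, 3 * t * (1 - t) ** 2, 3 * t**2 * (1 - t), t**3], axis=1
    )
    for _ in range(100):
        ctrl = rng.uniform(box_lo, box_hi, size=(4, 3))
        pts = bernstein @ ctrl
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if 20.0 <= length <= 200.0:
            return pts
    return pts  # pragma: no cover - the box makes the window near-certain


def _jitter_affine(rng: np.random.Generator, jitter: AffineJitter) -> np.ndarray:
    """Random small affine: Euler rotations, isotropic-ish scale, translation."""
    angles = np.deg2rad(
        rng.uniform(-jitter.max_rotation_deg, jitter.max_rotation_deg, size=3)
    )
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = np.diag(
        1.0 + rng.uniform(-jitter.max_scale_fraction, jitter.max_scale_fraction, size=3)
    )
    a = np.eye(4)
    a[:3, :3] = rz @ ry @ rx @ scale
    a[:3, 3] = rng.uniform(-jitter.max_translation_mm, jitter.max_translation_mm, size=3)
    return a


def sample_subject(
    spec: SyntheticCohortSpec, subject_index: int
) -> tuple[TractSet, np.ndarray, np.ndarray]:
    """Generate one subject: (tract set in subject space, labels,
    affine_to_reference).

    Subject 0 is the reference (identity affine).  Reproducible from
    (spec.seed, subject_index).
    """
    rng = np.random.default_rng([spec.seed, subject_index])
    box_lo = np.min([t.centerline.min(axis=0) for t in spec.templates], axis=0) - 10
    box_hi = np.max([t.centerline.max(axis=0) for t in spec.templates], axis=0) + 10

    polylines: list[np.ndarray] = []
    labels: list[str] = []
    for template in spec.templates:
        center = resample_polyline(template.centerline, RAW_POINTS)
        for _ in range(spec.tracts_per_bundle):
            disp = _smooth_displacement(
                rng, RAW_POINTS, spec.shape_noise_sd, template.tube_radius
            )
            pts = center + disp
            if rng.random() < spec.flip_probability:
                pts = pts[::-1]
            polylines.append(pts)
            labels.append(template.name)

    n_bundle_tracts = len(polylines)
    n_out = int(round(spec.outlier_fraction * n_bundle_tracts))
    for _ in range(n_out):
        pts = _random_bezier(rng, box_lo, box_hi)
        if rng.random() < spec.flip_probability:
            pts = pts[::-1]
        polylines.append(pts)
        labels.append(OUTLIER_TRUE)

    if subject_index == 0:
        affine = np.eye(4)
        affine_to_reference = np.eye(4)
    else:
        affine = _jitter_affine(rng, spec.subject_affine_jitter)
        affine_to_reference = np.linalg.inv(affine)

    lin, trans = affine[:3, :3], affine[:3, 3]
    tracts = [
        resample_tract(p @ lin.T + trans, spec.n_samples) for p in polylines
    ]
    return (
        TractSet(tracts=tracts, space_tag="subject"),
        np.array(labels),
        affine_to_reference,
    )


def build_synthetic_cohort(spec: SyntheticCohortSpec) -> list[SyntheticSubject]:
    """Generate the whole cohort; subject 0 is flagged as the reference."""
    cohort = []
    for s in range(spec.n_subjects):
        ts, labels, affine = sample_subject(spec, s)
        cohort.append(
            SyntheticSubject(
                tract_set=ts, labels=labels, affine_to_reference=affine,
                is_reference=(s == 0),
            )
        )
    return cohort
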