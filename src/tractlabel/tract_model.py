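"""Streamline representation and elementary flip-invariant distances.

A tractography streamline ("tract") is a 3D polyline.  For shape comparison
every tract is resampled to a fixed number ``n`` of points, uniformly spaced
in arc length along an interpolating cubic spline parameterized by chord
length, and flattened into a single vector

    f = (x1, y1, z1, ..., xn, yn, zn)

in 3n-dimensional space.  Streamlines carry no intrinsic direction, so the
tract-to-tract distance is the minimum of the Euclidean distance over the two
possible point orderings (flip invariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateInputError, ValidationError

DEFAULT_N_SAMPLES = 32

# Dense-subdivision factor for the arc-length reparameterization.  The
# chord-length cubic spline is evaluated at OVERSAMPLE * n parameter values
# and the uniform-arc-length samples are found by inverse linear
# interpolation of the cumulative polyline length (tolerance well below
# 1e-6 mm for smooth curves).
OVERSAMPLE = 20


@dataclass(frozen=True)
class Tract:
    """One streamline: raw polyline plus its fixed-length resampled vector."""

    raw_points: np.ndarray          # (m, 3) world mm
    vector: np.ndarray              # (3n,) flattened resampled points
    n_samples: int
    length_mm: float                # chord length of the resampled polyline

    @property
    def points(self) -> np.ndarray:
        """Resampled points as an (n, 3) array."""
        return self.vector.reshape(-1, 3)


@dataclass
class TractSet:
    """An indexed collection of tracts sharing one sampling resolution."""

    tracts: list[Tract]
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        if self.tracts:
            n0 = self.tracts[0].n_samples
            if any(t.n_samples != n0 for t in self.tracts):
                raise ValidationError("all tracts in a TractSet must share n_samples")

    def __len__(self) -> int:
        return len(self.tracts)

    @property
    def n_samples(self) -> int:
        if not self.tracts:
            raise ValidationError("empty TractSet has no n_samples")
        return self.tracts[0].n_samples

    def vectors(self) -> np.ndarray:
        """(N, 3n) matrix of resampled vectors."""
        return np.array([t.vector for t in self.tracts])

    def lengths(self) -> np.ndarray:
        return np.array([t.length_mm for t in self.tracts])


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points uniform in arc length.

    An interpolating cubic spline with chord-length knots is used when the
    input has >= 4 distinct points; shorter inputs fall back to piecewise
    linear interpolation.  The first and last output points coincide with
    the input endpoints.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValidationError(f"expected an (m, 3) array, got shape {points.shape}")
    if not np.all(np.isfinite(points)):
        raise ValidationError("polyline contains non-finite coordinates")
    if n < 2:
        raise ValidationError("need at least n=2 sample points")
    # drop consecutive duplicates so chord-length knots are strictly increasing
    if len(points) > 1:
        keep = np.ones(len(points), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 0
        points = points[keep]
    if len(points) < 2:
        raise DegenerateInputError("polyline has fewer than 2 distinct points")

    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    knots = np.concatenate([[0.0], np.cumsum(seg)])

    if n == 2:
        return np.array([points[0], points[-1]])

    if len(points) >= 4:
        spline = CubicSpline(knots, points, axis=0)
        t_dense = np.linspace(0.0, knots[-1], OVERSAMPLE * n)
        dense = spline(t_dense)
        s_dense = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        target = np.linspace(0.0, s_dense[-1], n)
        t_at = np.interp(target, s_dense, t_dense)
        out = spline(t_at)
    else:
        # piecewise-linear curve: chord length IS arc length
        target = np.linspace(0.0, knots[-1], n)
        out = np.column_stack(
            [np.interp(target, knots, points[:, d]) for d in range(3)]
        )
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def resample_tract(points: np.ndarray, n: int = DEFAULT_N_SAMPLES) -> Tract:
    """Build a :class:`Tract` from a raw polyline."""
    raw = np.asarray(points, dtype=float)
    sampled = resample_polyline(raw, n)
    length = _polyline_length(sampled)
    if length <= 0:
        raise DegenerateInputError("tract has zero length")
    return Tract(
        raw_points=raw,
        vector=sampled.reshape(-1),
        n_samples=n,
        length_mm=length,
    )


def reverse_vector(f: np.ndarray) -> np.ndarray:
    """Reverse the sample-point order of a flattened tract vector.

    Coordinate triples stay intact; applying twice returns the input.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.size % 3 != 0:
        raise ValidationError("tract vector length must be divisible by 3")
    return f.reshape(-1, 3)[::-1].reshape(-1)


def _check_pair(fi: np.ndarray, fj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fi = np.asarray(fi, dtype=float)
    fj = np.asarray(fj, dtype=float)
    if fi.shape != fj.shape:
        raise ValidationError(f"vector length mismatch: {fi.shape} vs {fj.shape}")
    return fi, fj


def euclidean_distance(fi: np.ndarray, fj: np.ndarray) -> float:
    """Euclidean distance between two tract vectors in 3n-space."""
    fi, fj = _check_pair(fi, fj)
    return float(np.linalg.norm(fi - fj))


def tract_distance(fi: np.ndarray, fj: np.ndarray) -> float:
    """Flip-invariant distance: min over the two orderings of ``fj``."""
    fi, fj = _check_pair(fi, fj)
    return min(euclidean_distance(fi, fj), euclidean_distance(fi, reverse_vector(fj)))


def pairwise_tract_distances(vectors: np.ndarray) -> np.ndarray:
    """Full (N, N) flip-invariant distance matrix for a stack of vectors."""
    from scipy.spatial.distance import cdist

    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] % 3 != 0:
        raise ValidationError("expected an (N, 3n) matrix of tract vectors")
    flipped = vectors.reshape(len(vectors), -1, 3)[:, ::-1, :].reshape(len(vectors), -1)
    d = np.minimum(cdist(vectors, vectors), cdist(vectors, flipped))
    # cdist(vectors, flipped) is not exactly symmetric in floating point
    d = np.minimum(d, d.T)
    np.fill_diagonal(d, 0.0)
    return d
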