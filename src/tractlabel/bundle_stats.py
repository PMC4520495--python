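"""Gaussian modeling of tract groups.

A shape-homogeneous group of tracts is summarized by a multivariate Gaussian
over the 3n-dimensional resampled vectors: the coordinate-wise mean and a
shrinkage covariance estimate.  With N tracts and 3n dimensions (typically
96), the empirical covariance is singular whenever N < 3n or the tracts are
nearly parallel, so the off-diagonal correlations are shrunk toward zero by
the data-driven intensity

    lambda* = sum_{i!=j} Var-hat(r_ij) / sum_{i!=j} r_ij**2

(Schafer-Strimmer estimator), which guarantees a full-rank covariance
regardless of the sample.  Group-to-tract similarity is the Mahalanobis
quadratic form (no square root; compared directly to chi-square critical
values), and group-to-group similarity is the symmetric Kullback-Leibler
divergence between the two Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import InsufficientDataError, ValidationError
from .tract_model import reverse_vector

# Coordinates duplicated exactly across all members would give 0/0
# correlations; their variance is floored (mm^2) before standardization.
VARIANCE_FLOOR = 1e-8

# When members are exactly collinear (all |r_ij| = 1, zero estimator
# variance) the raw intensity is 0 and the shrunk matrix would stay
# singular; this floor preserves the full-rank guarantee.
LAMBDA_FLOOR = 1e-6


@dataclass(frozen=True)
class GaussianGroupModel:
    """Gaussian model of a tract group with cached Cholesky factorization."""

    mean: np.ndarray        # (k,)
    cov: np.ndarray         # (k, k) shrinkage covariance
    n_members: int
    chol: np.ndarray        # lower-triangular L with L L^T = cov
    log_det: float          # ln det(cov)

    @property
    def dim(self) -> int:
        return self.mean.size

    @classmethod
    def from_members(cls, members: np.ndarray) -> "GaussianGroupModel":
        """Fit mean + shrinkage covariance from an (N, k) stack of vectors.

        Members must already be orientation-aligned.
        """
        members = np.asarray(members, dtype=float)
        m = group_mean(members)
        cov = shrinkage_covariance(members)
        return cls.from_moments(m, cov, n_members=len(members))

    @classmethod
    def from_moments(
        cls, mean: np.ndarray, cov: np.ndarray, n_members: int = 0
    ) -> "GaussianGroupModel":
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValidationError("covariance shape does not match mean")
        asym = np.abs(cov - cov.T).max()
        scale = max(np.abs(cov).max(), 1.0)
        if asym > 1e-9 * scale:
            raise ValidationError("covariance is not symmetric")
        try:
            c, _low = cho_factor(cov, lower=True)
            chol = np.tril(c)
        except np.linalg.LinAlgError:
            # Near-singular shrinkage output (e.g. the collinear-members
            # lambda floor) can defeat Cholesky on the covariance scale when
            # variances span a wide dynamic range.  Factorizing the
            # correlation matrix (unit diagonal, far better conditioned) and
            # rescaling its factor by the standard deviations is exact:
            # cov = D R D  =>  L_cov = D L_R.
            d = np.sqrt(np.diag(cov))
            if np.any(d <= 0):
                raise ValidationError("covariance has non-positive diagonal")
            corr = cov / np.outer(d, d)
            try:
                c, _low = cho_factor(corr, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValidationError(
                    f"covariance not positive definite: {exc}"
                ) from exc
            chol = d[:, None] * np.tril(c)
        log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return cls(mean=mean, cov=cov, n_members=n_members, chol=chol, log_det=log_det)


def group_mean(members: np.ndarray) -> np.ndarray:
    """Coordinate-wise arithmetic mean of a stack of aligned tract vectors."""
    members = np.asarray(members, dtype=float)
    if members.ndim == 1:
        members = members[None, :]
    if members.size == 0 or members.shape[0] < 1:
        raise ValidationError("group_mean needs at least one member")
    return members.mean(axis=0)


def shrinkage_covariance(members: np.ndarray) -> np.ndarray:
    """Shrinkage covariance estimate of an (N, k) stack of aligned vectors.

    The diagonal keeps the empirical unbiased variances (floored at
    ``VARIANCE_FLOOR``); off-diagonal entries are r*_ij sqrt(s_ii s_jj) with
    r*_ij = r_ij * min(1, max(0, 1 - lambda*)).  Var-hat(r_ij) is the
    unbiased empirical variance of the standardized cross-products,

        Var-hat(r_ij) = N / (N-1)^3 * sum_k (w_kij - wbar_ij)^2,
        w_kij = z_ki z_kj,   z = centered member / unbiased sd.

    The result is symmetric positive definite for any N >= 2.
    """
    members = np.asarray(members, dtype=float)
    if members.ndim != 2:
        raise ValidationError("members must be an (N, k) matrix")
    n, k = members.shape
    if n < 2:
        raise InsufficientDataError("shrinkage covariance needs >= 2 members")

    centered = members - members.mean(axis=0)
    var = (centered**2).sum(axis=0) / (n - 1)
    var = np.maximum(var, VARIANCE_FLOOR)
    sd = np.sqrt(var)
    z = centered / sd

    # empirical correlations and the variance of each r_ij
    r = (z.T @ z) / (n - 1)
    wbar = (z.T @ z) / n
    sq = (z**2).T @ (z**2)                      # sum_k w_kij^2
    var_r = n / (n - 1) ** 3 * (sq - n * wbar**2)

    off = ~np.eye(k, dtype=bool)
    denom = float((r[off] ** 2).sum())
    numer = float(var_r[off].sum())
    if denom <= 0.0:
        lam = 1.0                               # no correlation to keep: diagonal
    else:
        # The floor keeps the full-rank guarantee when members are (near-)
        # collinear, where the estimator variance underflows toward zero;
        # it perturbs the non-degenerate case by < 1e-6 relative.
        lam = max(numer / denom, LAMBDA_FLOOR)
    shrink = min(1.0, max(0.0, 1.0 - lam))

    r_star = r * shrink
    np.fill_diagonal(r_star, 1.0)
    cov = r_star * np.outer(sd, sd)
    return 0.5 * (cov + cov.T)


def reverse_model(model: GaussianGroupModel) -> GaussianGroupModel:
    """The same Gaussian with its sample-point order reversed.

    Reversal is the permutation P of coordinate triples: mean -> P m,
    covariance -> P S P^T (refactorized).
    """
    k = model.dim
    perm = np.arange(k).reshape(-1, 3)[::-1].reshape(-1)
    return GaussianGroupModel.from_moments(
        model.mean[perm], model.cov[np.ix_(perm, perm)], model.n_members
    )


def skld_flip(b_i: GaussianGroupModel, b_j: GaussianGroupModel) -> float:
    """Flip-invariant symmetric KLD: min over reversing one model's order.

    Each group's members are orientation-aligned to an arbitrary in-group
    reference, so two models of the same bundle may be stored in opposite
    sample orders; minimizing over the reversal mirrors the tract-level
    flip-invariant distances.  Symmetric in its arguments.
    """
    return min(skld(b_i, b_j), skld(reverse_model(b_i), b_j))


def mahalanobis(f: np.ndarray, model: GaussianGroupModel) -> float:
    """Mahalanobis quadratic form (f - m)^T S*^{-1} (f - m).

    Note: this is the squared-scale quantity; it is compared directly to
    chi-square critical values with k = 3n degrees of freedom.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != model.mean.shape:
        raise ValidationError("vector dimension does not match model")
    y = solve_triangular(model.chol, f - model.mean, lower=True)
    return float(y @ y)


def tract_group_distance(f: np.ndarray, model: GaussianGroupModel) -> float:
    """Flip-invariant tract-to-group distance: min Mahalanobis over orderings."""
    return min(mahalanobis(f, model), mahalanobis(reverse_vector(f), model))


def _trace_solve(a: GaussianGroupModel, b_cov: np.ndarray) -> float:
    """trace(S_a^{-1} S_b) via the cached factorization of ``a``."""
    return float(np.trace(cho_solve((a.chol, True), b_cov)))


def _quad(a: GaussianGroupModel, v: np.ndarray) -> float:
    """v^T S_a^{-1} v via the cached factorization."""
    y = solve_triangular(a.chol, v, lower=True)
    return float(y @ y)


def kld_gaussian(b_i: GaussianGroupModel, b_j: GaussianGroupModel) -> float:
    """KL divergence d_KL(b_i || b_j) between two Gaussian group models.

    Closed form: 1/2 (tr(S_j^{-1} S_i) + v^T S_j^{-1} v - ln det(S_j^{-1} S_i) - k)
    with v = m_j - m_i.
    """
    if b_i.dim != b_j.dim:
        raise ValidationError("model dimensions differ")
    k = b_i.dim
    v = b_j.mean - b_i.mean
    return 0.5 * (
        _trace_solve(b_j, b_i.cov) + _quad(b_j, v) - (b_i.log_det - b_j.log_det) - k
    )


def skld(b_i: GaussianGroupModel, b_j: GaussianGroupModel) -> float:
    """Symmetric KL divergence between two Gaussian group models.

    1/2 (tr(S_i^{-1} S_j) + tr(S_j^{-1} S_i) + v^T S_i^{-1} v + v^T S_j^{-1} v - 2k);
    the log-determinant terms of the two directed divergences cancel.
    """
    if b_i.dim != b_j.dim:
        raise ValidationError("model dimensions differ")
    k = b_i.dim
    v = b_j.mean - b_i.mean
    return 0.5 * (
        _trace_solve(b_i, b_j.cov)
        + _trace_solve(b_j, b_i.cov)
        + _quad(b_i, v)
        + _quad(b_j, v)
        - 2 * k
    )
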