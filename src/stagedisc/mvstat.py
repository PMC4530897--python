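"""Multivariate discriminability statistics over labeled voxel time series.

Given scans grouped into K task stages, the between-class (H) and
within-class (E) scatter matrices decompose the total scatter about the grand
mean.  The eigenvalues ``lam_i`` of ``H E^-1`` yield the three classical
MANOVA statistics:

* Wilks' lambda              ``prod 1 / (1 + lam_i)``  (1 = no separation)
* Lawley-Hotelling trace     ``sum lam_i``             (generalized T^2)
* Roy's greatest root        ``max lam_i``

Pairwise stage differences are squared Mahalanobis distances between stage
means under a shrinkage-regularized pooled within-class covariance
``sigma_hat = (1 - lambda) * Sigma + lambda * diag(Sigma)``.

No parametric F-approximations are provided: significance comes from the
block-permutation machinery in :mod:`stagedisc.permboot`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .prep import StageLabelSeries, VoxelTimeSeries

__all__ = [
    "ScatterPair",
    "StatTriple",
    "RegularizedCovariance",
    "StageDistanceMatrix",
    "scatter_matrices",
    "manova_stats",
    "regularized_cov",
    "mahalanobis_sq",
    "stage_distance_matrix",
    "phase_contrast",
]

#: default shrinkage weight for distance computations (configurable everywhere)
DEFAULT_SHRINKAGE = 0.1


@dataclass(frozen=True)
class ScatterPair:
    """Between-class (H) and within-class (E) scatter matrices.

    ``H + E`` equals the total scatter about the grand mean; both are
    symmetric and E is positive semi-definite.
    """

    H: np.ndarray
    E: np.ndarray
    class_counts: np.ndarray
    class_ids: np.ndarray
    grand_mean: np.ndarray
    class_means: np.ndarray  # (K, p)

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    @property
    def n_classes(self) -> int:
        return int(self.class_ids.size)


@dataclass(frozen=True)
class StatTriple:
    wilks_lambda: float
    lawley_hotelling: float
    roy_gcr: float


@dataclass(frozen=True)
class RegularizedCovariance:
    """``sigma_hat = (1 - lambda) * Sigma_pooled + lambda * diag(Sigma_pooled)``.

    Shrinking toward the diagonal leaves variances untouched, damps
    off-diagonal covariances, and guarantees positive definiteness for
    ``lambda > 0`` whenever all variances are positive.
    """

    sigma_hat: np.ndarray
    lambda_reg: float

    def cholesky(self) -> np.ndarray:
        try:
            return scipy.linalg.cholesky(self.sigma_hat, lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError(
                "covariance is not positive definite; increase lambda_reg"
            ) from exc


@dataclass(frozen=True)
class StageDistanceMatrix:
    """K x K squared Mahalanobis distances between stage means (zero diagonal)."""

    d2: np.ndarray
    n_stages: int


# ---------------------------------------------------------------------------


def _labeled_xy(ts: VoxelTimeSeries, labels: StageLabelSeries) -> tuple[np.ndarray, np.ndarray]:
    if ts.n_scans != labels.n_scans:
        raise ValueError("time series and labels disagree on scan count")
    mask = labels.labeled_mask
    return ts.data[mask], labels.labels[mask]


def scatter_from_arrays(x: np.ndarray, y: np.ndarray) -> ScatterPair:
    """Scatter decomposition on a raw (n, p) matrix with integer class labels."""
    class_ids, inv, counts = np.unique(y, return_inverse=True, return_counts=True)
    if class_ids.size < 2:
        raise ValueError("scatter_matrices requires at least 2 classes")
    small = class_ids[counts < 2]
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than 2 scans")
    p = x.shape[1]
    grand = x.mean(axis=0)
    # class sums via bincount per column
    sums = np.zeros((class_ids.size, p))
    np.add.at(sums, inv, x)
    means = sums / counts[:, None]
    dm = means - grand
    H = (dm * counts[:, None]).T @ dm
    resid = x - means[inv]
    E = resid.T @ resid
    H = 0.5 * (H + H.T)
    E = 0.5 * (E + E.T)
    return ScatterPair(
        H=H, E=E, class_counts=counts, class_ids=class_ids, grand_mean=grand, class_means=means
    )


def scatter_matrices(ts: VoxelTimeSeries, labels: StageLabelSeries) -> ScatterPair:
    """Between/within scatter over the labeled scans (label 0 excluded).

    ``H = sum_k n_k (mu_k - mu)(mu_k - mu)^T``;
    ``E = sum_k sum_{i in k} (x_i - mu_k)(x_i - mu_k)^T``.
    """
    x, y = _labeled_xy(ts, labels)
    if x.shape[0] == 0:
        raise ValueError("no labeled scans")
    return scatter_from_arrays(x, y)


def _he_eigenvalues(sp: ScatterPair, lambda_reg: float) -> np.ndarray:
    """Eigenvalues of H E^-1 via the symmetric-definite generalized problem
    (Cholesky whitening of the optionally shrunk E)."""
    E = sp.E
    if lambda_reg < 0 or lambda_reg > 1:
        raise ValueError("lambda_reg must lie in [0, 1]")
    if lambda_reg > 0:
        E = (1.0 - lambda_reg) * E + lambda_reg * np.diag(np.diag(E))
    try:
        L = scipy.linalg.cholesky(E, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter is singular; pass lambda_reg > 0 to shrink "
            "it toward its diagonal"
        ) from exc
    W = scipy.linalg.solve_triangular(L, sp.H, lower=True)
    M = scipy.linalg.solve_triangular(L, W.T, lower=True)
    M = 0.5 * (M + M.T)
    lam = scipy.linalg.eigvalsh(M)
    return np.clip(lam, 0.0, None)  # H is PSD, negatives are round-off


def manova_stats(sp: ScatterPair, lambda_reg: float = 0.0) -> StatTriple:
    """The three MANOVA statistics from the eigenvalues of ``H E^-1``."""
    lam = _he_eigenvalues(sp, lambda_reg)
    return StatTriple(
        wilks_lambda=float(np.prod(1.0 / (1.0 + lam))),
        lawley_hotelling=float(lam.sum()),
        roy_gcr=float(lam.max()),
    )


def regularized_cov(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    lambda_reg: float = DEFAULT_SHRINKAGE,
) -> RegularizedCovariance:
    """Pooled within-class covariance (divisor n - K) with diagonal shrinkage."""
    sp = scatter_matrices(ts, labels)
    return regularized_cov_from_scatter(sp, lambda_reg)


def regularized_cov_from_scatter(
    sp: ScatterPair, lambda_reg: float
) -> RegularizedCovariance:
    if lambda_reg < 0 or lambda_reg > 1:
        raise ValueError("lambda_reg must lie in [0, 1]")
    dof = sp.n - sp.n_classes
    if dof < 1:
        raise ValueError("need at least n - K >= 1 labeled scans for the pooled covariance")
    sigma = sp.E / dof
    sigma_hat = (1.0 - lambda_reg) * sigma + lambda_reg * np.diag(np.diag(sigma))
    return RegularizedCovariance(sigma_hat=0.5 * (sigma_hat + sigma_hat.T), lambda_reg=lambda_reg)


def mahalanobis_sq(a: np.ndarray, b: np.ndarray, cov: RegularizedCovariance) -> float:
    """Squared Mahalanobis distance ``(a-b) sigma_hat^-1 (a-b)^T``, computed
    through a Cholesky factorization (never an explicit inverse)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    L = cov.cholesky()
    z = scipy.linalg.solve_triangular(L, d, lower=True)
    return float(z @ z)


def stage_distance_matrix(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    lambda_reg: float = DEFAULT_SHRINKAGE,
) -> StageDistanceMatrix:
    """All pairwise squared Mahalanobis distances between stage means under
    the shared regularized pooled covariance."""
    sp = scatter_matrices(ts, labels)
    cov = regularized_cov_from_scatter(sp, lambda_reg)
    L = cov.cholesky()
    # whiten class means once, then pairwise Euclidean distances
    z = scipy.linalg.solve_triangular(L, sp.class_means.T, lower=True).T
    diff = z[:, None, :] - z[None, :, :]
    d2_present = np.einsum("jkp,jkp->jk", diff, diff)
    K = labels.n_stages
    d2 = np.full((K, K), np.nan)
    idx = sp.class_ids.astype(int) - 1
    for a, ia in enumerate(idx):
        for b, ib in enumerate(idx):
            d2[ia, ib] = d2_present[a, b]
    np.fill_diagonal(d2, 0.0)
    return StageDistanceMatrix(d2=d2, n_stages=K)


def phase_contrast(d2_norm: StageDistanceMatrix) -> tuple[float, float]:
    """Collapse a 6-stage distance matrix into the two task-phase scores.

    ``decision_making``  = mean distance of evidence stages 1-3 to the final
    (fourth) evidence stage, i.e. the build-up to the decision point;
    ``decision_evaluation`` = mean distance of stages 1-3 to the behavioral
    response and choice-rating stages (5, 6).

    Defined only for the canonical K = 6 design.
    """
    if d2_norm.n_stages != 6:
        raise ValueError("phase_contrast is specific to the 6-stage design")
    d2 = d2_norm.d2
    making = float(np.mean([d2[0, 3], d2[1, 3], d2[2, 3]]))
    evaluation = float(np.mean([d2[j, k] for j in (0, 1, 2) for k in (4, 5)]))
    return making, evaluation
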