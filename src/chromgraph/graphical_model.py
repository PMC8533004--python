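"""Sparse precision estimation with an elementwise L1 penalty.

Maximizes the penalized Gaussian log-likelihood

    log det(Theta) - tr(U Theta) - sum_{i != j} rho_ij * |Theta_ij|

by block coordinate ascent directly on the precision matrix: each
column/row subproblem reduces, via the Schur complement, to a Lasso with
per-coefficient penalties that is solved by coordinate descent. The
inverse ``W = Theta^{-1}`` is maintained with rank-one block updates, so
every column update is an exact block maximization and the objective trace
is non-decreasing. The diagonal is never penalized.

Partial correlations are derived as ``-Theta_ij / sqrt(Theta_ii Theta_jj)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from chromgraph.prior import PenaltyMatrix

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100
EDGE_ZERO_TOL = 1e-10


def _cd_lasso_py(M, b, rho, beta, max_iter, tol):
    """Coordinate descent for min 0.5 b'Mb + b.beta + sum rho|beta|."""
    p = beta.shape[0]
    Mbeta = M @ beta
    for _ in range(max_iter):
        delta_max = 0.0
        for k in range(p):
            old = beta[k]
            grad_rest = b[k] + Mbeta[k] - M[k, k] * old
            z = -grad_rest
            if abs(z) <= rho[k]:
                new = 0.0
            else:
                new = (z - np.sign(z) * rho[k]) / M[k, k]
            diff = new - old
            if diff != 0.0:
                beta[k] = new
                Mbeta += M[:, k] * diff
                if abs(diff) > delta_max:
                    delta_max = abs(diff)
        if delta_max <= tol:
            break
    return beta


try:  # optional numba acceleration; the pure-numpy path is equivalent
    from numba import njit

    @njit(cache=True)
    def _cd_lasso_nb(M, b, rho, beta, max_iter, tol):  # pragma: no cover
        p = beta.shape[0]
        Mbeta = M @ beta
        for _ in range(max_iter):
            delta_max = 0.0
            for k in range(p):
                old = beta[k]
                z = -(b[k] + Mbeta[k] - M[k, k] * old)
                if abs(z) <= rho[k]:
                    new = 0.0
                else:
                    if z > 0.0:
                        new = (z - rho[k]) / M[k, k]
                    else:
                        new = (z + rho[k]) / M[k, k]
                diff = new - old
                if diff != 0.0:
                    beta[k] = new
                    for l in range(p):
                        Mbeta[l] += M[l, k] * diff
                    if abs(diff) > delta_max:
                        delta_max = abs(diff)
            if delta_max <= tol:
                break
        return beta

    _cd_lasso = _cd_lasso_nb
except Exception:  # pragma: no cover - numba missing
    _cd_lasso = _cd_lasso_py


@dataclass
class PrecisionFit:
    """Result of a penalized precision fit."""

    theta: np.ndarray
    cov: np.ndarray
    rho: np.ndarray
    pcor: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    jitter: float = 0.0

    @property
    def n_edges(self) -> int:
        """Number of off-diagonal edges (upper triangle, |theta| above zero tol)."""
        mask = np.abs(np.triu(self.theta, k=1)) > EDGE_ZERO_TOL
        return int(mask.sum())


def empirical_covariance(X: np.ndarray) -> np.ndarray:
    """Maximum-likelihood covariance (1/m normalization), cells as rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (cells x bins)")
    m, p = X.shape
    if m < 2:
        raise ValueError("need at least 2 cells to estimate a covariance")
    if p < 2:
        raise ValueError("need at least 2 bins")
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / m


def penalized_objective(theta: np.ndarray, cov: np.ndarray, rho: np.ndarray) -> float:
    """log det(theta) - tr(cov @ theta) - sum_offdiag rho |theta|."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    pen = float(np.sum(rho * np.abs(theta))) - float(
        np.sum(np.diag(rho) * np.abs(np.diag(theta)))
    )
    return float(logdet - np.sum(cov * theta) - pen)


def _as_rho(rho, p: int) -> np.ndarray:
    if isinstance(rho, PenaltyMatrix):
        mat = rho.rho
    elif np.isscalar(rho):
        mat = np.full((p, p), float(rho))
    else:
        mat = np.asarray(rho, dtype=float)
    if mat.shape != (p, p):
        raise ValueError(f"penalty shape {mat.shape} does not match covariance ({p},{p})")
    if np.any(mat < 0):
        raise ValueError("penalty must be non-negative")
    if not np.allclose(mat, mat.T):
        raise ValueError("penalty must be symmetric")
    mat = mat.copy()
    np.fill_diagonal(mat, 0.0)  # diagonal never penalized
    return mat


def fit_glasso(
    cov: np.ndarray,
    rho,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    inner_max_iter: int = 1000,
    inner_tol: float = 1e-9,
) -> PrecisionFit:
    """Fit the elementwise-penalty graphical Lasso.

    Parameters
    ----------
    cov
        Symmetric empirical covariance. If singular, a jitter of
        ``1e-6 * trace / p`` is added to the diagonal.
    rho
        :class:`PenaltyMatrix`, dense symmetric array, or scalar.
    tol
        Relative objective-change convergence threshold across outer sweeps.
    max_iter
        Maximum outer sweeps over all columns.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    S = (S + S.T) / 2.0
    p = S.shape[0]
    rho_mat = _as_rho(rho, p)

    jitter = 0.0
    eigmin = float(np.linalg.eigvalsh(S)[0])
    if eigmin < 1e-12 * max(1.0, np.trace(S) / p):
        jitter = 1e-6 * np.trace(S) / p
        if jitter <= 0:
            jitter = 1e-6
        S = S + jitter * np.eye(p)
        logger.info("covariance near-singular (min eig %.3g): added jitter %.3g", eigmin, jitter)
    if np.any(np.diag(S) <= 0):
        raise ValueError("covariance diagonal must be positive after jitter")

    d = np.diag(S)
    theta = np.diag(1.0 / d)
    W = np.diag(d.copy())  # W = theta^{-1}, maintained exactly

    trace: list[float] = [penalized_objective(theta, S, rho_mat)]
    converged = False
    sweep = 0
    idx_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    for sweep in range(1, max_iter + 1):
        for j in range(p):
            idx = idx_cache[j]
            w12 = W[idx, j]
            w22 = W[j, j]
            W11 = W[np.ix_(idx, idx)]
            Q = W11 - np.outer(w12, w12) / w22  # = Theta11^{-1}
            s12 = S[idx, j]
            s22 = S[j, j]
            M = np.ascontiguousarray(s22 * Q)
            beta = theta[idx, j].copy()
            beta = _cd_lasso(M, s12.copy(), rho_mat[idx, j].copy(), beta,
                             inner_max_iter, inner_tol)
            Qb = Q @ beta
            theta[idx, j] = beta
            theta[j, idx] = beta
            theta[j, j] = 1.0 / s22 + float(beta @ Qb)
            W[np.ix_(idx, idx)] = Q + s22 * np.outer(Qb, Qb)
            W[idx, j] = -s22 * Qb
            W[j, idx] = -s22 * Qb
            W[j, j] = s22
        obj = penalized_objective(theta, S, rho_mat)
        trace.append(obj)
        prev = trace[-2]
        if np.isfinite(prev) and abs(obj - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break

    if not converged:
        warnings.warn(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(last objective change {trace[-1] - trace[-2]:.3g})",
            RuntimeWarning,
        )

    theta = (theta + theta.T) / 2.0
    eigmin_theta = float(np.linalg.eigvalsh(theta)[0])
    if eigmin_theta <= 0:
        raise RuntimeError(f"estimated precision not positive definite (min eig {eigmin_theta:.3g})")

    return PrecisionFit(
        theta=theta,
        cov=S,
        rho=rho_mat,
        pcor=partial_correlations(theta),
        objective_trace=trace,
        converged=converged,
        n_iter=sweep,
        jitter=jitter,
    )


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    """Partial correlations ``-theta_ij / sqrt(theta_ii theta_jj)``, unit diagonal."""
    theta = np.asarray(theta, dtype=float)
    diag = np.diag(theta)
    if np.any(diag <= 0):
        raise ValueError("precision diagonal must be positive")
    d = np.sqrt(diag)
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor
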