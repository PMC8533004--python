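"""Low-rank matrix completion by majorization-minimization.

Denoises the binned log-count matrix before covariance estimation. The
observed matrix ``Y`` is modelled as a masked sampling of a rank-``r``
matrix ``X = Uf @ Vf``; the masked Frobenius cost is minimized by
alternating least squares on a majorizing surrogate, with non-negative
truncation of the completed matrix after every iteration.

The mask operator is a binary elementwise (Hadamard) matrix: ``A(X) = A * X``
and its adjoint is itself. The majorization constant ``a`` must be at least
the spectral norm of the mask operator, which is 1 for a binary mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_RANK_CAP = 50
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-5


@dataclass
class FactorizationState:
    """State of one MM factorization run."""

    Y: np.ndarray
    A: np.ndarray
    Xk: np.ndarray
    Uf: np.ndarray
    Vf: np.ndarray
    B: np.ndarray | None
    a: float
    r: int
    k: int = 0


@dataclass
class FactorizationResult:
    X: np.ndarray
    cost_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    singular_values: np.ndarray | None = None


def default_rank(m: int, n: int) -> int:
    """Default target rank: min(50, floor(min(m, n) / 2)), at least 1."""
    return max(1, min(DEFAULT_RANK_CAP, min(m, n) // 2))


def svd_init(X: np.ndarray, r: int) -> np.ndarray:
    """Initial right factor: the top-``r`` right singular vectors of ``X``.

    Returns an ``r x n`` matrix with orthonormal rows.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix must be finite")
    if r < 1 or r > min(m, n):
        raise ValueError(f"rank r={r} must satisfy 1 <= r <= min(m, n)={min(m, n)}")
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return vt[:r]


def majorize_step(Y: np.ndarray, A: np.ndarray, Xk: np.ndarray, a: float) -> np.ndarray:
    """Surrogate target ``B = Xk + (1/a) * A * (Y - A * Xk)``."""
    if a <= 0:
        raise ValueError(f"majorization constant a={a} must be positive")
    A = np.asarray(A, dtype=float)
    return Xk + (A * (Y - A * Xk)) / a


def update_factors(
    B: np.ndarray, Uf: np.ndarray, Vf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating least-squares pair of factor updates against ``B``.

    ``Uf`` is refit with ``Vf`` fixed, then ``Vf`` with the new ``Uf`` fixed;
    rank-deficient factors fall back to the pseudoinverse solution, so the
    Frobenius objective is non-increasing across the pair.
    """
    Uf_new = np.linalg.lstsq(Vf.T, B.T, rcond=None)[0].T
    Vf_new = np.linalg.lstsq(Uf_new, B, rcond=None)[0]
    return Uf_new, Vf_new


def mm_factorize(
    Y: np.ndarray,
    A: np.ndarray | None = None,
    r: int | None = None,
    a: float = 1.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> FactorizationResult:
    """Complete ``Y`` with a rank-``r`` non-negative matrix.

    Parameters
    ----------
    Y
        Observed matrix (cells x bins); entries outside the mask are ignored.
    A
        Binary mask, 1 where observed. ``None`` means fully observed.
    r
        Target rank; defaults to :func:`default_rank`.
    a
        Majorization step constant; must be >= 1 for a binary mask.
    max_iter, tol
        Stop when the relative change of the masked cost drops below
        ``tol`` or after ``max_iter`` iterations.
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    if A is None:
        A = np.ones_like(Y)
    else:
        A = (np.asarray(A) != 0).astype(float)
        if A.shape != Y.shape:
            raise ValueError("mask shape must match Y")
    if a < 1.0:
        raise ValueError(f"a={a} < 1 does not majorize a binary mask operator")
    if r is None:
        r = default_rank(m, n)
    if r < 1 or r > min(m, n):
        raise ValueError(f"rank r={r} must satisfy 1 <= r <= min(m, n)={min(m, n)}")

    if not A.any():
        logger.warning("all-zero mask: nothing observed, returning zero matrix")
        return FactorizationResult(
            X=np.zeros_like(Y), cost_trace=[0.0], converged=True, n_iter=0
        )

    Y0 = A * Y
    _, s, vt = np.linalg.svd(Y0, full_matrices=False)
    Vf = vt[:r]
    Uf = Y0 @ Vf.T  # Vf rows orthonormal -> least-squares fit of Y0

    Xk = np.clip(Uf @ Vf, 0.0, None)
    cost = float(np.sum((A * (Y - Xk)) ** 2))
    trace = [cost]
    converged = False
    k = 0
    for k in range(1, max_iter + 1):
        B = majorize_step(Y, A, Xk, a)
        Uf, Vf = update_factors(B, Uf, Vf)
        Xk = np.clip(Uf @ Vf, 0.0, None)
        cost = float(np.sum((A * (Y - Xk)) ** 2))
        trace.append(cost)
        prev = trace[-2]
        if abs(prev - cost) <= tol * max(prev, 1e-30):
            converged = True
            break
    return FactorizationResult(
        X=Xk, cost_trace=trace, converged=converged, n_iter=k, singular_values=s
    )
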