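"""Independent reference implementations used only by the test suite.

These deliberately take different algorithmic routes from the package:
a proximal-gradient (ISTA with backtracking) solver for the penalized
precision estimate, a naive two-pass covariance, and a permutation-based
two-sample proportion test.
"""

from __future__ import annotations

import numpy as np


def prox_grad_glasso(cov, rho_mat, max_iter=20000, tol=1e-12, t0=1.0):
    """Minimize -logdet(T) + tr(cov T) + sum_offdiag rho|T| by ISTA.

    Backtracking halves the step until the iterate is positive definite and
    satisfies the quadratic upper-bound condition. Returns the precision.
    """
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    rho_mat = np.asarray(rho_mat, dtype=float).copy()
    np.fill_diagonal(rho_mat, 0.0)

    def smooth(T):
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return np.inf
        return -logdet + np.sum(cov * T)

    def prox(T, step):
        out = np.sign(T) * np.maximum(np.abs(T) - step * rho_mat, 0.0)
        np.fill_diagonal(out, np.diag(T))
        return out

    T = np.diag(1.0 / np.diag(cov))
    f = smooth(T)
    t = t0
    for _ in range(max_iter):
        grad = cov - np.linalg.inv(T)
        while True:
            T_new = prox(T - t * grad, t)
            T_new = (T_new + T_new.T) / 2.0
            f_new = smooth(T_new)
            if np.isfinite(f_new):
                diff = T_new - T
                bound = f + np.sum(grad * diff) + np.sum(diff * diff) / (2.0 * t)
                if f_new <= bound + 1e-15:
                    break
            t *= 0.5
            if t < 1e-14:
                raise RuntimeError("prox-grad line search failed")
        delta = np.max(np.abs(T_new - T))
        T, f = T_new, f_new
        t *= 1.25  # tentative step growth
        if delta < tol:
            break
    return T


def brute_force_covariance(X):
    """Two-pass ML covariance with explicit loops over variable pairs."""
    X = np.asarray(X, dtype=float)
    m, p = X.shape
    means = [sum(X[:, j]) / m for j in range(p)]
    cov = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            s = 0.0
            for i in range(m):
                s += (X[i, a] - means[a]) * (X[i, b] - means[b])
            cov[a, b] = s / m
    return cov


def permutation_proportion_test(hits_case, total_case, hits_null, total_null,
                                n_perm=10_000, seed=0):
    """Two-sided permutation p-value for a difference of two proportions."""
    rng = np.random.default_rng(seed)
    total_hits = hits_case + hits_null
    n = total_case + total_null
    obs = abs(hits_case / total_case - hits_null / total_null)
    draws = rng.hypergeometric(total_hits, n - total_hits, total_case, size=n_perm)
    p1 = draws / total_case
    p0 = (total_hits - draws) / total_null
    return float(np.mean(np.abs(p1 - p0) >= obs - 1e-12))


def penalized_objective_ref(theta, cov, rho_mat):
    """Reference penalized log-likelihood (maximization form)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    rho_mat = np.asarray(rho_mat, dtype=float).copy()
    np.fill_diagonal(rho_mat, 0.0)
    return float(logdet - np.sum(cov * theta) - np.sum(rho_mat * np.abs(theta)))
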