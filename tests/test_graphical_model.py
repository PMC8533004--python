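import numpy as np
import pytest

from chromgraph.graphical_model import (
    EDGE_ZERO_TOL,
    empirical_covariance,
    fit_glasso,
    partial_correlations,
    penalized_objective,
)
from oracles import brute_force_covariance, prox_grad_glasso, penalized_objective_ref


class TestEmpiricalCovariance:
    def test_identical_cells_give_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (2, 1))
        np.testing.assert_array_equal(empirical_covariance(X), np.zeros((3, 3)))

    def test_ml_normalization(self):
        # 2 cells, values {0, 2} -> variance 1 under 1/m
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        cov = empirical_covariance(X)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(200, 50))
        np.testing.assert_allclose(
            empirical_covariance(X), brute_force_covariance(X), atol=1e-12
        )

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            empirical_covariance(np.ones((1, 5)))

    def test_psd(self, rng):
        cov = empirical_covariance(rng.normal(size=(10, 30)))
        assert np.linalg.eigvalsh(cov)[0] >= -1e-10


class TestFitGlasso:
    def test_identity_cov_zero_penalty(self):
        fit = fit_glasso(np.eye(5), 0.0, tol=1e-12)
        np.testing.assert_allclose(fit.theta, np.eye(5), atol=1e-8)

    def test_2x2_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = fit_glasso(S, 0.0, tol=1e-14, max_iter=1000)
        expected = np.array([[1.0, -0.5], [-0.5, 1.0]]) / 0.75
        np.testing.assert_allclose(fit.theta, expected, atol=1e-6)

    def test_matches_prox_grad_oracle_elementwise_penalty(self, rng):
        for _ in range(3):
            p = 8
            A = rng.normal(size=(5 * p, p))
            S = A.T @ A / (5 * p) + 0.2 * np.eye(p)
            R = rng.uniform(0, 0.3, size=(p, p))
            R = (R + R.T) / 2
            np.fill_diagonal(R, 0.0)
            ref = prox_grad_glasso(S, R)
            fit = fit_glasso(S, R, tol=1e-12, max_iter=1000)
            assert np.abs(fit.theta - ref).max() < 1e-4
            assert abs(
                penalized_objective_ref(fit.theta, S, R)
                - penalized_objective_ref(ref, S, R)
            ) < 1e-4

    def test_matches_sklearn_uniform_penalty(self, rng):
        from sklearn.covariance import graphical_lasso

        p = 8
        A = rng.normal(size=(80, p))
        S = A.T @ A / 80 + 0.3 * np.eye(p)
        _, prec = graphical_lasso(S, alpha=0.05, tol=1e-10, max_iter=5000)
        fit = fit_glasso(S, 0.05, tol=1e-12, max_iter=1000)
        assert np.abs(fit.theta - prec).max() < 1e-4

    def test_rho_zero_limit_is_inverse(self, rng):
        p = 6
        A = rng.normal(size=(60, p))
        S = A.T @ A / 60 + 0.5 * np.eye(p)
        fit = fit_glasso(S, 0.0, tol=1e-14, max_iter=2000)
        assert np.abs(fit.theta - np.linalg.inv(S)).max() <= 1e-6

    def test_large_penalty_gives_diagonal(self, rng):
        p = 6
        A = rng.normal(size=(60, p))
        S = A.T @ A / 60 + 0.5 * np.eye(p)
        fit = fit_glasso(S, 100.0, tol=1e-12)
        off = fit.theta - np.diag(np.diag(fit.theta))
        assert np.abs(off).max() < EDGE_ZERO_TOL
        np.testing.assert_allclose(np.diag(fit.theta), 1.0 / np.diag(S), rtol=1e-8)

    def test_objective_trace_monotone(self, rng):
        p = 10
        A = rng.normal(size=(50, p))
        S = A.T @ A / 50 + 0.1 * np.eye(p)
        R = rng.uniform(0, 0.2, size=(p, p))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 0.0)
        fit = fit_glasso(S, R, tol=1e-12, max_iter=200)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs >= -1e-9)

    def test_sparsity_monotone_in_penalty_scale(self, rng):
        p = 12
        A = rng.normal(size=(40, p))
        S = A.T @ A / 40 + 0.1 * np.eye(p)
        base = rng.uniform(0.01, 0.1, size=(p, p))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
        counts = []
        for factor in [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]:
            fit = fit_glasso(S, factor * base, tol=1e-10, max_iter=500)
            counts.append(fit.n_edges)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_singular_cov_gets_jitter(self, rng):
        # more variables than observations: rank-deficient covariance
        X = rng.normal(size=(5, 12))
        S = empirical_covariance(X)
        fit = fit_glasso(S, 0.1, tol=1e-8)
        assert fit.jitter > 0
        assert np.linalg.eigvalsh(fit.theta)[0] > 0

    def test_asymmetric_cov_rejected(self):
        with pytest.raises(ValueError):
            fit_glasso(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_glasso(np.eye(3), -0.1)

    def test_penalized_objective_infeasible_is_minus_inf(self):
        theta = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        assert penalized_objective(theta, np.eye(2), np.zeros((2, 2))) == -np.inf

    def test_nonconvergence_warns(self, rng):
        p = 10
        A = rng.normal(size=(50, p))
        S = A.T @ A / 50 + 0.1 * np.eye(p)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_glasso(S, 0.05, tol=0.0, max_iter=2)
        assert not fit.converged


class TestPartialCorrelations:
    def test_formula(self):
        theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
        pcor = partial_correlations(theta)
        assert pcor[0, 1] == pytest.approx(0.5)
        assert pcor[0, 0] == 1.0

    def test_diagonal_theta_gives_zero_offdiag(self):
        pcor = partial_correlations(np.diag([2.0, 3.0, 4.0]))
        assert np.all(pcor[np.triu_indices(3, k=1)] == 0)

    def test_chain_precision_zero_pcor_nonzero_marginal(self):
        # edges 0-1 and 1-2 only: pcor_02 = 0 but marginal corr_02 != 0
        theta = np.array([[1.5, -0.6, 0.0], [-0.6, 1.8, -0.6], [0.0, -0.6, 1.5]])
        assert np.linalg.eigvalsh(theta)[0] > 0
        pcor = partial_correlations(theta)
        assert pcor[0, 2] == 0.0
        cov = np.linalg.inv(theta)
        marginal = cov[0, 2] / np.sqrt(cov[0, 0] * cov[2, 2])
        assert abs(marginal) > 0.05

    def test_range(self, rng):
        A = rng.normal(size=(30, 6))
        theta = np.linalg.inv(A.T @ A / 30 + 0.5 * np.eye(6))
        theta = (theta + theta.T) / 2
        pcor = partial_correlations(theta)
        assert np.all(np.abs(pcor) <= 1 + 1e-12)
        np.testing.assert_array_equal(pcor, pcor.T)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            partial_correlations(np.array([[0.0, 0.0], [0.0, 1.0]]))
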