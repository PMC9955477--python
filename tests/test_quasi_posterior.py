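import numpy as np
import pytest

from qbimc.core import BilinearDataset, ObservedEntries
from qbimc.prior import PriorConfig, grad_log_prior, log_prior
from qbimc.quasi_posterior import (
    QuasiPosterior,
    coefficient_from_predictor,
    empirical_risk_full,
    empirical_risk_observed,
    posterior_mean_predictor,
)

from .test_prior import finite_diff_grad


def toy_instance(seed, n=6, p=5, k=4, q=3, C=np.inf, sigma=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((k, q))
    M_star = rng.standard_normal((p, k))
    Y = X @ M_star @ Z + sigma * rng.standard_normal((n, q))
    return BilinearDataset(X, Z, Y, C=C), M_star


class TestEmpiricalRiskFull:
    def test_perfect_fit_is_zero(self):
        data, M_star = toy_instance(0, sigma=0.0)
        assert empirical_risk_full(M_star, data) == pytest.approx(0.0, abs=1e-20)

    def test_scalar_case(self):
        d = BilinearDataset([[1.0]], [[1.0]], [[2.0]], C=10)
        assert empirical_risk_full(np.array([[0.0]]), d) == pytest.approx(4.0)

    def test_truncation_active(self):
        d = BilinearDataset([[1.0]], [[1.0]], [[2.0]], C=1)
        assert empirical_risk_full(np.array([[5.0]]), d) == pytest.approx(1.0)

    def test_pythagoras_for_noiseless_data(self):
        # Y = X M* Z exactly: risk(M) equals the prediction discrepancy
        data, M_star = toy_instance(1, sigma=0.0)
        M = np.random.default_rng(2).standard_normal(M_star.shape)
        lhs = empirical_risk_full(M, data)
        D = data.X @ (M - M_star) @ data.Z
        assert lhs == pytest.approx(np.sum(D * D) / (data.n * data.q), rel=1e-12)


class TestEmpiricalRiskObserved:
    def test_exact_entry_gives_zero(self):
        data, M_star = toy_instance(3, sigma=0.0)
        v = (data.X @ M_star @ data.Z)[0, 0]
        obs = ObservedEntries.from_triplets([(1, 1, v)], data.n, data.q)
        assert empirical_risk_observed(M_star, data.X, data.Z, obs) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_duplicates_each_count(self):
        X, Z = np.array([[1.0]]), np.array([[1.0]])
        obs = ObservedEntries.from_triplets(
            [(1, 1, 2.0), (1, 1, 0.0)], 1, 1, with_replacement=True
        )
        # (XMZ)_{11} = 1: ((2-1)^2 + (0-1)^2)/2 = 1
        assert empirical_risk_observed(np.array([[1.0]]), X, Z, obs, C=10) == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((3, 2))
        Z = rng.standard_normal((2, 2))
        M = rng.standard_normal((2, 2))
        trip = [(1, 1, 0.3), (2, 2, -1.0), (3, 1, 0.5), (1, 1, 0.9)]
        obs = ObservedEntries.from_triplets(trip, 3, 2, with_replacement=True)
        T = np.clip(X @ M @ Z, -0.8, 0.8)
        manual = np.mean([(v - T[i - 1, j - 1]) ** 2 for i, j, v in trip])
        got = empirical_risk_observed(M, X, Z, obs, C=0.8)
        assert got == pytest.approx(manual, rel=1e-12)

    def test_quasi_posterior_risk_agrees_with_function(self):
        data, _ = toy_instance(5)
        trip = [(1, 1, 0.5), (2, 3, 1.0), (4, 2, -0.2)]
        obs = ObservedEntries.from_triplets(trip, data.n, data.q)
        prior = PriorConfig(tau=1.0, p=data.p, k=data.k)
        qp = QuasiPosterior((data.X, data.Z, obs), 3.0, prior)
        M = np.random.default_rng(6).standard_normal((data.p, data.k))
        assert qp.risk(M) == pytest.approx(
            empirical_risk_observed(M, data.X, data.Z, obs), rel=1e-12
        )


class TestLogQuasiPosterior:
    def test_lambda_zero_is_prior_only(self):
        data, _ = toy_instance(7)
        prior = PriorConfig(tau=1.0, p=data.p, k=data.k)
        qp = QuasiPosterior(data, 0.0, prior)
        M = np.random.default_rng(8).standard_normal((data.p, data.k))
        assert qp.logpdf(M) == pytest.approx(log_prior(M, prior), rel=1e-12)
        np.testing.assert_allclose(qp.grad(M), grad_log_prior(M, prior), rtol=1e-10)

    def test_composition_of_components(self):
        data, _ = toy_instance(9)
        prior = PriorConfig(tau=0.8, p=data.p, k=data.k)
        lam = 2.5
        qp = QuasiPosterior(data, lam, prior)
        M = np.random.default_rng(10).standard_normal((data.p, data.k))
        expected = -lam * empirical_risk_full(M, data) + log_prior(M, prior)
        assert qp.logpdf(M) == pytest.approx(expected, rel=1e-12)

    def test_scalar_arithmetic(self):
        # r(M) = 4, log-prior 0 at M = 0, lambda = 2 -> -8
        d = BilinearDataset([[1.0]], [[1.0]], [[2.0]], C=10)
        qp = QuasiPosterior(d, 2.0, PriorConfig(tau=1.0, p=1, k=1))
        assert qp.logpdf(np.array([[0.0]])) == pytest.approx(-8.0)

    def test_full_vs_observed_representation(self):
        # a full dataset and the triplet list of every cell give the same
        # tempered risk when lambda/(nq) matches lambda/m
        data, _ = toy_instance(11, C=np.inf)
        trip = [
            (i + 1, j + 1, data.Y[i, j])
            for i in range(data.n)
            for j in range(data.q)
        ]
        obs = ObservedEntries.from_triplets(trip, data.n, data.q)
        prior = PriorConfig(tau=1.0, p=data.p, k=data.k)
        lam = 17.0
        qp_full = QuasiPosterior(data, lam, prior)
        qp_obs = QuasiPosterior((data.X, data.Z, obs), lam, prior)
        M = np.random.default_rng(12).standard_normal((data.p, data.k))
        assert qp_full.logpdf(M) == pytest.approx(qp_obs.logpdf(M), rel=1e-10)


class TestGradient:
    @pytest.mark.parametrize("C", [np.inf, 1.5])
    def test_full_data_finite_differences(self, C):
        data, _ = toy_instance(13, C=C)
        prior = PriorConfig(tau=0.6, p=data.p, k=data.k)
        qp = QuasiPosterior(data, 4.0, prior)
        M = 0.3 * np.random.default_rng(14).standard_normal((data.p, data.k))
        g = qp.grad(M)
        g_fd = finite_diff_grad(qp.logpdf, M)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-7)

    def test_observed_data_finite_differences(self):
        data, _ = toy_instance(15)
        trip = [(1, 1, 0.4), (2, 2, -0.6), (5, 3, 1.2), (2, 2, 0.1)]
        obs = ObservedEntries.from_triplets(trip, data.n, data.q, with_replacement=True)
        prior = PriorConfig(tau=1.0, p=data.p, k=data.k)
        qp = QuasiPosterior((data.X, data.Z, obs), 5.0, prior, C=2.0)
        M = 0.2 * np.random.default_rng(16).standard_normal((data.p, data.k))
        g = qp.grad(M)
        g_fd = finite_diff_grad(qp.logpdf, M)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-7)

    def test_clamped_entry_has_zero_data_gradient(self):
        # single cell with |XMZ| > C: the tempered-risk part of the gradient
        # vanishes, leaving exactly the prior gradient
        d = BilinearDataset([[1.0]], [[1.0]], [[2.0]], C=1.0)
        prior = PriorConfig(tau=1.0, p=1, k=1)
        qp = QuasiPosterior(d, 3.0, prior)
        M = np.array([[5.0]])
        np.testing.assert_allclose(qp.grad(M), grad_log_prior(M, prior), atol=1e-14)


class TestPosteriorMeanPredictor:
    def test_singleton_average(self):
        data, M_star = toy_instance(17)
        P = posterior_mean_predictor([M_star], data.X, data.Z, C=2.0)
        np.testing.assert_allclose(
            P, np.clip(data.X @ M_star @ data.Z, -2, 2), rtol=1e-12
        )

    def test_symmetric_pair_cancels(self):
        data, M_star = toy_instance(18)
        P = posterior_mean_predictor([M_star, -M_star], data.X, data.Z)
        np.testing.assert_allclose(P, 0.0, atol=1e-12)

    def test_matches_loop_oracle(self):
        data, _ = toy_instance(19)
        rng = np.random.default_rng(20)
        samples = [rng.standard_normal((data.p, data.k)) for _ in range(3)]
        C = 1.2
        manual = sum(np.clip(data.X @ M @ data.Z, -C, C) for M in samples) / 3
        got = posterior_mean_predictor(samples, data.X, data.Z, C=C)
        np.testing.assert_allclose(got, manual, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            posterior_mean_predictor([], np.eye(2), np.eye(2))


class TestCoefficientFromPredictor:
    def test_identity_designs(self):
        P = np.random.default_rng(21).standard_normal((4, 4))
        np.testing.assert_allclose(
            coefficient_from_predictor(P, np.eye(4), np.eye(4)), P, rtol=1e-12
        )

    def test_recovers_coefficient_on_invertible_instance(self):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((3, 3))
        Z = rng.standard_normal((3, 3))
        M = rng.standard_normal((3, 3))
        got = coefficient_from_predictor(X @ M @ Z, X, Z)
        np.testing.assert_allclose(got, M, atol=1e-9)

    def test_rank_deficient_matches_least_squares(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((6, 3)) @ np.array([[1.0, 0, 1], [0, 1, 0], [0, 0, 0]])
        Z = rng.standard_normal((2, 4))
        P = rng.standard_normal((6, 4))
        M_hat = coefficient_from_predictor(P, X, Z)
        # normal equations of the bilinear least-squares problem hold
        resid = X.T @ (P - X @ M_hat @ Z) @ Z.T
        scale = np.linalg.norm(X.T @ P @ Z.T)
        assert np.linalg.norm(resid) <= 1e-8 * max(scale, 1.0)
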