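"""Open N-mixture likelihood, diagnostics, and empirical-Bayes prediction.

The load-bearing checks here compare the forward-recursion likelihood and
the forward-backward posterior against exhaustive enumeration over all
latent trajectories — a brute-force oracle that shares no code with the
recursion it validates.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from nestmix.data_model import CountDataset
from nestmix.dm_density import (
    DMParameters,
    FittedDMModel,
    closure_change,
    closure_test,
    check_K_stability,
    fit_dm,
    initial_pmf,
    latent_posterior,
    predict_density,
    quadratic_vertex,
    site_log_likelihood,
    transition_pmf,
    transition_matrix,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def enumerate_site_likelihood(y, mask, lam, p, gamma, omega, K,
                              mixture="poisson", alpha=None):
    """Sum P(trajectory) * P(y | trajectory) over all (N_1..N_T) in {0..K}^T."""
    T = len(y)
    init = initial_pmf(lam, mixture, K, alpha)
    total = 0.0
    for traj in itertools.product(range(K + 1), repeat=T):
        pr = init[traj[0]]
        for t in range(1, T):
            pr *= transition_pmf(traj[t - 1], gamma, omega, K)[traj[t]]
        for t in range(T):
            if mask[t]:
                pr *= stats.binom.pmf(y[t], traj[t], p[t])
        total += pr
    return np.log(total) if total > 0 else -np.inf


def enumerate_posterior_initial(y, mask, lam, p, gamma, omega, K):
    """Brute-force Bayes: posterior over N_1 given the whole count history."""
    T = len(y)
    init = initial_pmf(lam, "poisson", K)
    post = np.zeros(K + 1)
    for traj in itertools.product(range(K + 1), repeat=T):
        pr = init[traj[0]]
        for t in range(1, T):
            pr *= transition_pmf(traj[t - 1], gamma, omega, K)[traj[t]]
        for t in range(T):
            if mask[t]:
                pr *= stats.binom.pmf(y[t], traj[t], p[t])
        post[traj[0]] += pr
    return post / post.sum()


def make_fit(y, mask, beta_lambda, beta_p, gamma, omega, K,
             plot_covs=None, density_covs=(), detection_covs=()):
    """Assemble a FittedDMModel at chosen parameters without fitting."""
    M = y.shape[0]
    data = CountDataset([f"s{i}" for i in range(M)], y, mask, {},
                        plot_covs)
    par = DMParameters(np.asarray(beta_lambda, float), np.asarray(beta_p, float),
                       np.log(gamma) if gamma > 0 else -20.0,
                       special.logit(omega) if omega < 1 else 20.0, None, K)
    n = par.pack().size
    return FittedDMModel(par, np.zeros((n, n)), 0.0, n, data,
                         list(density_covs), list(detection_covs), "poisson",
                         True, 0.0)


# ---------------------------------------------------------------------------
# elementary pmfs


class TestInitialPmf:
    def test_poisson_closed_form(self):
        pmf = initial_pmf(1.0, "poisson", K=10)
        assert pmf[0] == pytest.approx(np.exp(-1), rel=1e-12)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-7)

    def test_degenerate_small_lambda(self):
        pmf = initial_pmf(1e-12, "poisson", K=5)
        assert pmf[0] == pytest.approx(1.0, abs=1e-10)

    def test_negbin_matches_independent_formula(self):
        # textbook NB(mean mu, dispersion alpha) written out via gammaln
        lam, alpha, K = 2.0, 2.16, 50
        n = np.arange(K + 1)
        logpmf = (special.gammaln(n + alpha) - special.gammaln(alpha)
                  - special.gammaln(n + 1)
                  + alpha * np.log(alpha / (alpha + lam))
                  + n * np.log(lam / (alpha + lam)))
        np.testing.assert_allclose(initial_pmf(lam, "negbin", K, alpha),
                                   np.exp(logpmf), rtol=1e-10)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            initial_pmf(1.0, "negbin", 10, alpha=None)
        with pytest.raises(ValueError):
            initial_pmf(1.0, "poisson", K=-1)


class TestTransitionPmf:
    def test_closure_limit_is_identity(self):
        row = transition_pmf(4, gamma=0.0, omega=1.0, K=10)
        expected = np.zeros(11)
        expected[4] = 1.0
        np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_no_survivors_reduces_to_poisson(self):
        row = transition_pmf(0, gamma=0.5, omega=0.3, K=10)
        np.testing.assert_allclose(row, stats.poisson.pmf(np.arange(11), 0.5),
                                   rtol=1e-12)

    def test_matches_monte_carlo(self):
        m, omega, gamma, K = 3, 0.87, 0.2, 20
        rng = np.random.default_rng(42)
        n = 200_000
        draws = rng.binomial(m, omega, n) + rng.poisson(gamma, n)
        row = transition_pmf(m, gamma, omega, K)
        for k in range(6):
            freq = np.mean(draws == k)
            se = np.sqrt(row[k] * (1 - row[k]) / n)
            assert abs(freq - row[k]) < 3 * se + 1e-12

    def test_rows_sum_to_one_minus_truncation(self):
        Tm = transition_matrix(0.2, 0.87, 30)
        sums = Tm.sum(axis=1)
        assert np.all(sums <= 1.0 + 1e-12)
        # far from the truncation bound the lost mass is negligible
        np.testing.assert_allclose(sums[:20], 1.0, atol=1e-8)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            transition_pmf(5, 0.1, 0.5, K=3)
        with pytest.raises(ValueError):
            transition_pmf(1, -0.1, 0.5, K=3)


# ---------------------------------------------------------------------------
# likelihood


class TestSiteLogLikelihood:
    def test_perfect_detection_single_occasion_collapses_to_mixture(self):
        ll = site_log_likelihood([3], [True], 2.0, [1.0], 0.0, 1.0, K=20)
        assert ll == pytest.approx(stats.poisson.logpmf(3, 2.0), rel=1e-10)

    def test_closure_contradiction_is_impossible(self):
        ll = site_log_likelihood([2, 3], [True, True], 2.0, [1.0, 1.0],
                                 0.0, 1.0, K=20)
        assert ll == -np.inf

    def test_matches_enumeration_on_fixed_case(self):
        y, mask = [1, 3], [True, True]
        lam, p = 2.3, [0.4, 0.7]
        ll = site_log_likelihood(y, mask, lam, p, 0.3, 0.8, K=12)
        oracle = enumerate_site_likelihood(y, mask, lam, p, 0.3, 0.8, 12)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_skips_unobserved_occasions(self):
        # masking the second occasion must equal enumeration that skips it
        y, mask = [2, 0, 1], [True, False, True]
        ll = site_log_likelihood(y, mask, 1.5, [0.5, 0.5, 0.5], 0.1, 0.9, K=10)
        oracle = enumerate_site_likelihood(y, mask, 1.5, [0.5] * 3, 0.1, 0.9, 10)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_count_above_K_rejected(self):
        with pytest.raises(ValueError, match="truncation"):
            site_log_likelihood([7], [True], 1.0, [0.5], 0.0, 1.0, K=5)

    def test_random_draws_match_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            T = rng.integers(1, 4)
            K = int(rng.integers(4, 13))
            lam = rng.uniform(0.2, 4.0)
            p = rng.uniform(0.05, 0.95, T)
            gamma = rng.uniform(0, 1.0)
            omega = rng.uniform(0, 1)
            y = rng.integers(0, min(4, K), T)
            mask = rng.random(T) > 0.2
            if not mask.any():
                mask[0] = True
            ll = site_log_likelihood(y, mask, lam, p, gamma, omega, K)
            oracle = enumerate_site_likelihood(y, mask, lam, p, gamma, omega, K)
            np.testing.assert_allclose(ll, oracle, atol=1e-10)


# ---------------------------------------------------------------------------
# fitting


class TestFitDM:
    def test_recovers_closed_perfect_detection(self):
        rng = np.random.default_rng(5)
        M, T, lam = 200, 3, 2.0
        N = rng.poisson(lam, M)
        y = np.tile(N[:, None], (1, T))
        data = CountDataset([str(i) for i in range(M)], y,
                            np.ones((M, T), bool))
        fit = fit_dm(data, [], [], K=int(y.max()) + 20, n_starts=1,
                     fix_gamma=0.0, fix_omega=1.0)
        lam_hat = float(np.exp(fit.parameters.beta_lambda[0]))
        p_hat = float(fit.parameters.beta_p[0])
        # with closed dynamics and repeated identical counts p -> 1, lambda -> mean(N)
        assert special.expit(p_hat) > 0.99
        mc_se = np.sqrt(lam / M)
        assert abs(lam_hat * special.expit(p_hat) - lam) < 3 * mc_se

    def test_all_zero_counts_flags_boundary(self):
        M, T = 20, 2
        data = CountDataset([str(i) for i in range(M)],
                            np.zeros((M, T), int), np.ones((M, T), bool))
        fit = fit_dm(data, [], [], K=10, n_starts=1)
        assert np.exp(fit.parameters.beta_lambda[0]) < 0.05
        assert any("boundary" in w for w in fit.warnings)

    def test_K_below_max_count_rejected(self):
        data = CountDataset(["a"], np.array([[5]]), np.array([[True]]))
        with pytest.raises(ValueError, match="K below"):
            fit_dm(data, [], [], K=3)

    def test_n_params_excludes_pinned_parameters(self):
        data = CountDataset(["a", "b"], np.array([[1, 1], [0, 1]]),
                            np.ones((2, 2), bool))
        free = fit_dm(data, [], [], K=8, n_starts=1)
        pinned = fit_dm(data, [], [], K=8, n_starts=1, fix_gamma=0.0)
        assert free.n_params == pinned.n_params + 1


class TestKStability:
    def test_poisson_fit_is_K_stable(self, default_fit):
        report = check_K_stability(default_fit, increments=(20,))
        assert report["stable"]
        assert report["max_abs_coef_change"] < 0.01
        # truncation-convergence: the likelihood has stopped moving in K
        assert abs(report["table"]["loglik_change"].iloc[0]) < 1e-6


class TestClosure:
    def test_paper_magnitude_decline(self):
        # gamma ~ 0, omega = 0.87: a 13% decline per between-survey interval
        change = closure_change(0.00002, 0.87)
        assert change == pytest.approx(-12.998, abs=1e-3)

    def test_equilibrium_is_zero_change(self):
        assert closure_change(0.0, 1.0) == 0.0

    def test_growth_is_positive(self):
        assert closure_change(0.3, 1.0) == pytest.approx(30.0)

    def test_closure_test_detects_open_population(self, default_fit):
        out = closure_test(default_fit)
        assert out["percent_change_per_interval"] == pytest.approx(
            closure_change(out["gamma_hat"], out["omega_hat"]))
        assert set(out) >= {"gamma_ci", "omega_ci", "closed"}


# ---------------------------------------------------------------------------
# empirical-Bayes posterior


class TestLatentPosterior:
    def test_perfect_detection_degenerate_at_counts(self):
        y = np.array([[2, 2], [0, 0], [3, 3]])
        fit = make_fit(y, np.ones((3, 2), bool), [np.log(2.0)], [20.0],
                       gamma=0.0, omega=1.0, K=10)
        post = latent_posterior(fit)
        np.testing.assert_array_equal(post.modes, y[:, 0])
        assert post.initial()[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_matches_enumeration_oracle(self):
        y = np.array([[1, 2]])
        lam, p, gamma, omega, K = 2.5, 0.45, 0.3, 0.8, 8
        fit = make_fit(y, np.ones((1, 2), bool), [np.log(lam)],
                       [special.logit(p)], gamma, omega, K)
        post = latent_posterior(fit)
        oracle = enumerate_posterior_initial(y[0], [True, True], lam,
                                             [p, p], gamma, omega, K)
        np.testing.assert_allclose(post.initial()[0], oracle, atol=1e-10)

    def test_posteriors_normalized(self, default_fit):
        post = latent_posterior(default_fit)
        sums = post.occasion_posteriors.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_detection_correction_raises_abundance(self, default_fit):
        # with p < 1 the corrected abundance must exceed the raw counts
        post = latent_posterior(default_fit)
        raw = default_fit.data.y[:, 0]
        assert post.modes.mean() > raw.mean()


# ---------------------------------------------------------------------------
# prediction


class TestPredictDensity:
    def test_intercept_at_covariate_means(self):
        y = np.array([[1, 1]])
        covs = pd.DataFrame({"forb_cover": [0.0]}, index=["s0"])
        fit = make_fit(y, np.ones((1, 2), bool), [0.7, 0.3], [0.0],
                       0.1, 0.9, 10, plot_covs=covs,
                       density_covs=["forb_cover"])
        out = predict_density(fit, covs)
        assert out["lambda_hat"].iloc[0] == pytest.approx(np.exp(0.7))

    def test_quadratic_vertices_from_reported_scale(self):
        # forb-cover quadratic peaks near 11.7%, slope quadratic near 2.4 deg
        assert quadratic_vertex(0.49, -0.021) == pytest.approx(11.667, abs=1e-3)
        assert quadratic_vertex(0.34, -0.07) == pytest.approx(2.4286, abs=1e-3)
        with pytest.raises(ValueError):
            quadratic_vertex(1.0, 0.0)

    def test_unknown_covariate_rejected(self, default_fit):
        bad = pd.DataFrame({"nonesuch": [0.0]})
        fit2 = FittedDMModel(default_fit.parameters, default_fit.covariance,
                             default_fit.log_likelihood, default_fit.n_params,
                             default_fit.data, ["biomass"], [], "poisson",
                             True, 0.0)
        with pytest.raises(KeyError):
            predict_density(fit2, bad)
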