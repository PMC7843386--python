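import warnings

import numpy as np
import pytest
from scipy import stats

from sced import (
    BUCPParams,
    BUCPPriors,
    MCMCSettings,
    SCEDSeries,
    SimScenario,
    log_likelihood,
    precision_to_sd,
    sample_posterior,
    sd_to_precision,
    simulate_sced,
    tau_full_conditional,
    tau_support,
)


def ar1_dense_loglik(series, params):
    """Dense-covariance oracle: MVN with Sigma_ij = sigma_e^2 rho^|i-j|."""
    n = series.n
    t = np.arange(1, n + 1)
    mu = np.where(t <= params.tau, params.beta1, params.beta2)
    idx = np.arange(n)
    cov = params.sigma_e**2 * params.rho ** np.abs(idx[:, None] - idx[None, :])
    return stats.multivariate_normal(mean=mu, cov=cov).logpdf(series.values)


class TestLogLikelihood:
    @pytest.mark.parametrize(
        "rho,sigma,tau", [(0.6, 1.0, 6), (-0.4, 2.5, 4), (0.0, 0.7, 8), (0.9, 0.3, 5)]
    )
    def test_matches_dense_covariance_oracle(self, noisy_series, rho, sigma, tau):
        params = BUCPParams(beta1=0.1, beta2=2.7, rho=rho, sigma_eps=sigma, tau=tau)
        assert log_likelihood(noisy_series, params) == pytest.approx(
            ar1_dense_loglik(noisy_series, params), rel=1e-10
        )

    def test_rho_zero_reduces_to_independent_normals(self, step_series):
        params = BUCPParams(beta1=1.0, beta2=5.0, rho=0.0, sigma_eps=0.5, tau=6)
        mu = np.where(np.arange(1, 13) <= 6, 1.0, 5.0)
        expected = stats.norm(mu, 0.5).logpdf(step_series.values).sum()
        assert log_likelihood(step_series, params) == pytest.approx(expected)

    def test_stationary_marginal_sd(self):
        # rho = 0.6, sigma_eps = 1 -> marginal SD 1/sqrt(1 - 0.36) = 1.25
        params = BUCPParams(beta1=0, beta2=1, rho=0.6, sigma_eps=1.0, tau=3)
        assert params.sigma_e == pytest.approx(1.25)

    def test_literal_init_variance_uses_innovation_sd(self, step_series):
        params = BUCPParams(beta1=1.0, beta2=5.0, rho=0.6, sigma_eps=0.5, tau=6)
        ll_stat = log_likelihood(step_series, params, init_variance="stationary")
        ll_lit = log_likelihood(step_series, params, init_variance="literal")
        delta = stats.norm(1.0, 0.5).logpdf(step_series.values[0]) - stats.norm(
            1.0, params.sigma_e
        ).logpdf(step_series.values[0])
        assert ll_lit - ll_stat == pytest.approx(delta)

    @pytest.mark.parametrize("rho,sigma", [(1.0, 1.0), (-1.2, 1.0), (0.2, 0.0), (0.2, -1)])
    def test_invalid_parameters_rejected(self, rho, sigma):
        with pytest.raises(ValueError):
            BUCPParams(beta1=0, beta2=1, rho=rho, sigma_eps=sigma, tau=5)


class TestTauFullConditional:
    def test_matches_enumeration_of_log_likelihood(self, noisy_series):
        params = BUCPParams(beta1=0.2, beta2=2.8, rho=0.3, sigma_eps=1.1)
        support, probs = tau_full_conditional(noisy_series, params)
        logliks = np.array(
            [
                log_likelihood(
                    noisy_series,
                    BUCPParams(0.2, 2.8, 0.3, 1.1, tau=int(k)),
                )
                for k in support
            ]
        )
        expected = np.exp(logliks - logliks.max())
        expected /= expected.sum()
        np.testing.assert_allclose(probs, expected, atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_huge_step_concentrates_at_true_change_point(self):
        scen = SimScenario(n_a=8, n_b=8, beta1=0, beta2=50, sigma_eps=1, rho=0.0)
        series, truth = simulate_sced(scen, 3)
        params = BUCPParams(beta1=0, beta2=50, rho=0.0, sigma_eps=1.0)
        support, probs = tau_full_conditional(series, params)
        assert probs[support == truth["true_tau"]][0] > 0.99

    def test_constant_series_gives_uniform_conditional(self):
        series = SCEDSeries(values=np.full(12, 4.2), design_cp=6)
        params = BUCPParams(beta1=4.2, beta2=4.2, rho=0.1, sigma_eps=1.0)
        support, probs = tau_full_conditional(series, params)
        np.testing.assert_allclose(probs, 1.0 / support.size, atol=1e-12)

    def test_support_rule(self):
        assert tau_support(6).tolist() == [3]
        assert tau_support(33).tolist() == list(range(3, 31))
        with pytest.raises(ValueError):
            tau_support(5)


class TestPriors:
    def test_hypermean_precision_to_sd(self):
        assert precision_to_sd(BUCPPriors().beta_hypermean_precision) == pytest.approx(100.0)
        assert sd_to_precision(100.0) == pytest.approx(1e-4)

    def test_tau_prior_uniform_and_normalised(self):
        support, mass = BUCPPriors().tau_prior(20)
        assert support[0] == 3 and support[-1] == 17
        assert mass.sum() == pytest.approx(1.0)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            BUCPPriors(beta_precision_shape=-1)
        with pytest.raises(ValueError):
            BUCPPriors(rho_low=0.5, rho_high=0.2)


class TestSampler:
    def _settings(self, **kw):
        base = dict(n_chains=2, n_adapt=300, n_samples=800, seed=11)
        base.update(kw)
        return MCMCSettings(**base)

    def test_same_seed_reproduces_draws_bitwise(self, noisy_series):
        p1 = sample_posterior(noisy_series, settings=self._settings())
        p2 = sample_posterior(noisy_series, settings=self._settings())
        for name in ("beta1", "beta2", "rho", "sigma_eps", "tau"):
            np.testing.assert_array_equal(p1.flat(name), p2.flat(name))

    def test_different_seed_differs(self, noisy_series):
        p1 = sample_posterior(noisy_series, settings=self._settings())
        p2 = sample_posterior(noisy_series, settings=self._settings(seed=12))
        assert not np.array_equal(p1.flat("beta1"), p2.flat("beta1"))

    def test_stationary_identity_on_every_draw(self, noisy_series):
        post = sample_posterior(noisy_series, settings=self._settings())
        np.testing.assert_allclose(
            post.sigma_e * np.sqrt(1.0 - post.rho**2),
            post.sigma_eps,
            rtol=1e-12,
        )

    def test_tau_draws_stay_in_prior_support(self, noisy_series):
        post = sample_posterior(noisy_series, settings=self._settings())
        taus = post.flat("tau")
        assert taus.min() >= 3 and taus.max() <= noisy_series.n - 3

    def test_phase_b_shift_moves_beta2_only(self, noisy_series):
        """Location equivariance: +c on phase B shifts the beta2 posterior by c."""
        post = sample_posterior(noisy_series, settings=self._settings())
        c = 7.5
        y2 = noisy_series.values.copy()
        y2[noisy_series.design_cp - 1 :] += c
        shifted = SCEDSeries(values=y2, design_cp=noisy_series.design_cp)
        post2 = sample_posterior(shifted, settings=self._settings())
        assert post2.flat("beta2").mean() - post.flat("beta2").mean() == pytest.approx(
            c, abs=0.15
        )
        assert post2.flat("beta1").mean() == pytest.approx(
            post.flat("beta1").mean(), abs=0.15
        )
        assert post2.flat("rho").mean() == pytest.approx(post.flat("rho").mean(), abs=0.1)
        assert post2.flat("sigma_eps").mean() == pytest.approx(
            post.flat("sigma_eps").mean(), abs=0.1
        )

    def test_tau_mode_recovers_clean_step(self):
        scen = SimScenario(n_a=15, n_b=15, beta1=0, beta2=5, sigma_eps=1, rho=0.2)
        series, truth = simulate_sced(scen, 5)
        post = sample_posterior(series, settings=self._settings(n_samples=1500))
        taus = post.flat("tau")
        values, counts = np.unique(taus, return_counts=True)
        assert values[np.argmax(counts)] == truth["true_tau"] == 15

    def test_nonconvergence_is_warning_not_error(self, noisy_series):
        """Whatever the PSRF outcome, a short run returns a posterior object."""
        settings = self._settings(n_adapt=0, n_samples=120, n_chains=2, seed=1)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            post = sample_posterior(noisy_series, settings=settings)
        assert post.n_draws == 240
        psrf_warnings = [w for w in caught if "PSRF" in str(w.message)]
        assert len(psrf_warnings) == len(post.warnings_)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_samples=0)
        with pytest.raises(ValueError):
            MCMCSettings(init_variance="bogus")

    def test_rho_acceptance_in_adapted_band(self, noisy_series):
        post = sample_posterior(noisy_series, settings=self._settings(n_adapt=1000))
        for rate in post.rho_acceptance:
            assert 0.1 < rate < 0.65
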