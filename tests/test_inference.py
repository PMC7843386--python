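import numpy as np
import pytest
from hypothesis import given
from hypothesis import settings as hsettings
from hypothesis import strategies as st

from sced import (
    MCMCSettings,
    SCEDSeries,
    classify_immediacy,
    discrete_hdi_set,
    effect_size_draws,
    hdi,
    rope_test,
    sample_posterior,
)
from sced.inference import EffectSizeDraws


def hdi_scan_oracle(draws, mass):
    """Exhaustive scan over every window of ceil(mass*n) sorted draws."""
    x = np.sort(draws)
    n = x.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        lo, hi = x[i], x[i + m - 1]
        if best is None or hi - lo < best[1] - best[0]:
            best = (lo, hi)
    return best


class TestHdi:
    def test_integer_ladder(self):
        lo, hi = hdi(np.arange(1, 101, dtype=float), 0.95)
        # every 95-point window has the same width; leftmost wins
        assert (lo, hi) == (1.0, 95.0)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.5, 0.8, 0.95]))
    @hsettings(max_examples=25, deadline=None)
    def test_matches_exhaustive_scan(self, seed, mass):
        rng = np.random.default_rng(seed)
        draws = rng.gamma(2.0, 1.5, size=rng.integers(100, 400))
        assert hdi(draws, mass) == hdi_scan_oracle(draws, mass)

    def test_symmetric_sample_close_to_equal_tails(self, rng):
        draws = rng.standard_normal(200_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 3.3), 0.95)
        assert lo == hi == 3.3

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50), 0.95)

    def test_discrete_highest_mass_set_not_contiguous(self):
        draws = np.array([3] * 50 + [7] * 45 + [5] * 5)
        assert discrete_hdi_set(draws, 0.95) == [3, 7]


class TestEffectSize:
    def _posterior(self, noisy_series, **kw):
        return sample_posterior(
            noisy_series,
            settings=MCMCSettings(n_chains=2, n_adapt=300, n_samples=600, seed=4, **kw),
        )

    def test_single_draw_value(self):
        # (61.2 - 33.9) / 5.0 = 5.46
        assert (61.2 - 33.9) / 5.0 == pytest.approx(5.46)

    def test_equal_intercepts_give_zero(self, noisy_series):
        post = self._posterior(noisy_series)
        post.beta2 = post.beta1.copy()
        es = effect_size_draws(post)
        assert np.all(es.values == 0.0)

    def test_standardizers_agree_when_rho_zero(self, noisy_series):
        post = self._posterior(noisy_series, fix_rho=0.0)
        es_innov = effect_size_draws(post, "innovation_sd")
        es_marg = effect_size_draws(post, "marginal_sd")
        np.testing.assert_allclose(es_innov.values, es_marg.values)

    def test_marginal_standardizer_shrinks_es(self, noisy_series):
        post = self._posterior(noisy_series)
        es_innov = effect_size_draws(post, "innovation_sd").values
        es_marg = effect_size_draws(post, "marginal_sd").values
        assert np.all(np.abs(es_marg) <= np.abs(es_innov) + 1e-12)

    def test_unknown_standardizer(self, noisy_series):
        post = self._posterior(noisy_series)
        with pytest.raises(ValueError, match="standardizer"):
            effect_size_draws(post, "phase_sd")


class TestRope:
    def _es(self, values):
        return EffectSizeDraws(values=np.asarray(values, float), standardizer="innovation_sd")

    def test_clear_effect_accepted(self, rng):
        es = self._es(rng.uniform(4.6, 6.4, 1000))
        d = rope_test(es, threshold=3.0)
        assert d.decision == "accept_effect"
        assert d.hdi_low >= 4.6 and d.fraction_above == 1.0

    def test_wide_interval_undecided(self, rng):
        es = self._es(np.linspace(0.14, 5.37, 1000))
        d = rope_test(es, threshold=3.0)
        assert d.decision == "undecided"

    def test_null_accepted_inside_rope(self, rng):
        es = self._es(rng.uniform(-0.5, 0.5, 1000))
        assert rope_test(es, threshold=3.0).decision == "accept_null"

    def test_boundary_inclusive(self):
        es = self._es(np.full(1000, 3.0))
        assert rope_test(es, threshold=3.0).decision == "accept_effect"

    @given(st.floats(0.01, 10.0))
    @hsettings(max_examples=30, deadline=None)
    def test_positive_shift_never_flips_to_null(self, shift):
        rng = np.random.default_rng(7)
        base = rng.normal(3.5, 0.1, 1000)
        before = rope_test(self._es(base)).decision
        after = rope_test(self._es(base + shift)).decision
        assert before == "accept_effect" and after != "accept_null"


class TestImmediacy:
    def _post_with_tau(self, noisy_series, taus):
        post = sample_posterior(
            noisy_series,
            settings=MCMCSettings(n_chains=1, n_adapt=100, n_samples=len(taus), seed=0),
        )
        post.tau = np.asarray(taus, dtype=int).reshape(1, -1)
        return post

    def test_point_mass_at_design_change_point(self, noisy_series):
        taus = [noisy_series.design_cp - 1] * 400
        v = classify_immediacy(self._post_with_tau(noisy_series, taus), noisy_series)
        assert v.category == "immediate"
        assert v.mass_at_mode == 1.0 and v.tau_posterior_sd == 0.0

    def test_concentration_after_intervention_is_delayed(self, noisy_series):
        # dominant mode 3 points after the intervention started
        taus = [noisy_series.design_cp + 2] * 350 + [noisy_series.design_cp - 1] * 50
        v = classify_immediacy(self._post_with_tau(noisy_series, taus), noisy_series)
        assert v.category == "delayed"
        assert v.tau_mode == noisy_series.design_cp + 2

    def test_uniform_posterior_is_unclear(self, noisy_series):
        taus = list(range(3, noisy_series.n - 2)) * 30
        v = classify_immediacy(self._post_with_tau(noisy_series, taus), noisy_series)
        assert v.category == "unclear"

    def test_tied_modes_flag_multimodality(self, noisy_series):
        cp = noisy_series.design_cp
        taus = [cp - 1] * 200 + [cp + 1] * 200
        v = classify_immediacy(self._post_with_tau(noisy_series, taus), noisy_series)
        assert v.multimodal and v.category == "unclear"
        assert v.tau_mode == cp - 1  # smallest among tied modes

    def test_rescaling_outcome_leaves_tau_posterior_unchanged(self, noisy_series):
        settings = MCMCSettings(n_chains=2, n_adapt=300, n_samples=800, seed=9)
        post = sample_posterior(noisy_series, settings=settings)
        scaled = SCEDSeries(
            values=3.0 * noisy_series.values + 11.0, design_cp=noisy_series.design_cp
        )
        post_s = sample_posterior(scaled, settings=settings)
        v1 = classify_immediacy(post, noisy_series)
        v2 = classify_immediacy(post_s, scaled)
        assert v1.tau_mode == v2.tau_mode
        assert v1.category == v2.category
        # tau marginals agree within Monte-Carlo error
        for k in range(3, noisy_series.n - 2):
            m1 = np.mean(post.flat("tau") == k)
            m2 = np.mean(post_s.flat("tau") == k)
            assert m1 == pytest.approx(m2, abs=0.07)


def test_posterior_plot_written(tmp_path, noisy_series):
    post = sample_posterior(
        noisy_series, settings=MCMCSettings(n_chains=1, n_adapt=100, n_samples=300, seed=2)
    )
    out = tmp_path / "post.png"
    from sced.inference import plot_posterior

    plot_posterior(post, str(out))
    assert out.exists() and out.stat().st_size > 0
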