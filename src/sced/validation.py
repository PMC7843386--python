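"""Independent cross-checks of the BUCP sampler.

These routines deliberately avoid the sampler's whitened-likelihood code
path: the exact change-point marginal is computed from the dense AR(1)
covariance via ``scipy.stats.multivariate_normal`` with the intercepts and
their hypermean integrated out analytically and the beta-precision prior
integrated by quadrature.  Feasible because the intercept block is Gaussian
and the change point lives on a few discrete values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .bucp import BUCPPriors, MCMCSettings, sample_posterior, tau_support
from .io import SCEDSeries
from .synthetic import SimScenario, simulate_sced

__all__ = ["exact_tau_marginal", "tau_total_variation", "sbc_ranks"]


def exact_tau_marginal(
    series: SCEDSeries,
    rho: float,
    sigma_eps: float,
    priors: BUCPPriors | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior p(tau | y, rho, sigma_eps) under the default hierarchy.

    For each admissible change point k, the marginal likelihood integrates
    the intercepts analytically: with beta_j ~ N(m, 1/h) and
    m ~ N(mu0, 1/p0), the series is Gaussian with covariance

        Sigma(h) = sigma_e^2 * rho^|i-j|  +  (1/h) X X'  +  (1/p0) 1 1'

    (X the phase-indicator design for change point k, sigma_e the
    stationary marginal error SD), leaving one smooth quadrature over the
    Gamma prior on h.
    """
    priors = priors or BUCPPriors()
    y = series.values
    n = y.size
    support = tau_support(n)
    idx = np.arange(n)
    sigma_e2 = sigma_eps**2 / (1.0 - rho * rho)
    err_cov = sigma_e2 * rho ** np.abs(idx[:, None] - idx[None, :])
    hyper_cov = (1.0 / priors.beta_hypermean_precision) * np.ones((n, n))
    mean = np.full(n, priors.beta_hypermean_mean)

    a, b = priors.beta_precision_shape, priors.beta_precision_rate
    t = np.arange(1, n + 1)

    def log_marg(k: int, h: float) -> float:
        in_a = (t <= k).astype(float)
        X = np.column_stack([in_a, 1.0 - in_a])
        cov = err_cov + hyper_cov + (X @ X.T) / h
        return float(stats.multivariate_normal(mean=mean, cov=cov).logpdf(y))

    # shared offset keeps the integrands in a safe floating range
    offset = max(log_marg(int(k), 1.0) for k in support)
    vals = np.empty(support.size)
    for j, k in enumerate(support):
        integrand = lambda h: np.exp(log_marg(int(k), h) - offset) * stats.gamma.pdf(
            h, a=a, scale=1.0 / b
        )
        vals[j], _ = quad(integrand, 0.0, np.inf, limit=200)
    probs = vals / vals.sum()  # uniform tau prior cancels
    return support, probs


def tau_total_variation(
    series: SCEDSeries,
    rho: float,
    sigma_eps: float,
    n_draws: int = 50_000,
    seed: int = 0,
    priors: BUCPPriors | None = None,
    n_adapt: int = 1000,
) -> float:
    """TV distance between the MCMC tau marginal (rho, sigma fixed at the
    given values) and the exact enumeration of :func:`exact_tau_marginal`."""
    priors = priors or BUCPPriors()
    settings = MCMCSettings(
        n_chains=1,
        n_adapt=n_adapt,
        n_samples=n_draws,
        seed=seed,
        fix_rho=rho,
        fix_sigma_eps=sigma_eps,
    )
    post = sample_posterior(series, priors, settings)
    support, exact = exact_tau_marginal(series, rho, sigma_eps, priors)
    counts = np.array([(post.flat("tau") == k).sum() for k in support], dtype=float)
    mcmc = counts / counts.sum()
    return 0.5 * float(np.abs(mcmc - exact).sum())


def sbc_ranks(
    n: int = 8,
    n_reps: int = 150,
    n_posterior: int = 19,
    seed: int = 0,
    params: tuple[str, ...] = ("beta1", "sigma_eps"),
    thin: int = 40,
    n_adapt: int = 300,
) -> dict[str, np.ndarray]:
    """Simulation-based calibration ranks for the full sampler.

    Each replicate draws a parameter vector from the prior, simulates a
    length-n series from the model, fits it, and records the rank of the
    truth among ``n_posterior`` thinned posterior draws.  For a correct
    sampler the ranks are uniform on {0, ..., n_posterior}.
    """
    priors = BUCPPriors()
    rng = np.random.default_rng(seed)
    support = tau_support(n)
    ranks = {p: np.empty(n_reps, dtype=int) for p in params}
    for rep in range(n_reps):
        m = priors.beta_hypermean_mean + rng.standard_normal() / np.sqrt(
            priors.beta_hypermean_precision
        )
        h = rng.gamma(priors.beta_precision_shape, 1.0 / priors.beta_precision_rate)
        b1, b2 = m + rng.standard_normal(2) / np.sqrt(h)
        rho = rng.uniform(priors.rho_low, priors.rho_high)
        lam = rng.gamma(priors.error_precision_shape, 1.0 / priors.error_precision_rate)
        sigma = 1.0 / np.sqrt(lam)
        tau = int(rng.choice(support))
        truth = {"beta1": b1, "beta2": b2, "rho": rho, "sigma_eps": sigma, "tau": tau}

        scen = SimScenario(
            n_a=tau,  # generator true tau = n_a + latency with latency 0
            n_b=n - tau,
            beta1=b1,
            beta2=b2,
            sigma_eps=sigma,
            rho=rho,
            latency=0,
        )
        series, _ = simulate_sced(scen, rng)
        settings = MCMCSettings(
            n_chains=1,
            n_adapt=n_adapt,
            n_samples=n_posterior,
            thin=thin,
            seed=int(rng.integers(2**31)),
        )
        post = sample_posterior(series, priors, settings)
        for p in params:
            ranks[p][rep] = int(np.sum(post.flat(p) < truth[p]))
    return ranks
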