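"""Bayesian unknown change-point (BUCP) model for two-phase SCED series.

Model
-----
The outcome is piecewise-constant in the mean with AR(1) errors::

    y_t = mu_t + e_t,          mu_t = beta1 if t <= tau else beta2
    e_t = rho * e_{t-1} + eps_t,   eps_t ~ Normal(0, sigma_eps^2)

``tau`` is the *last baseline-regime* time point (an integer latent
variable), ``rho`` the lag-1 autocorrelation and ``sigma_eps`` the
innovation SD.  The stationary marginal SD of the error process is
``sigma_e = sigma_eps / sqrt(1 - rho^2)``; by default the first
observation of the series uses this marginal variance (``init_variance=
"stationary"``), with ``"literal"`` using sigma_eps^2 instead.

Priors (relatively uninformative, all configurable):

* beta_j ~ Normal(m, 1/h) with m ~ Normal(0, precision 1e-4)
  (SD 100) and h ~ Gamma(shape 1, rate 1),
* rho ~ Uniform(-1, 1),
* 1/sigma_eps^2 ~ Gamma(shape 1, rate 1),
* tau uniform on {3, ..., n-3} (at least three observations per phase).

Sampling is Metropolis-within-Gibbs: conditional on (rho, sigma_eps, tau)
the series is whitened by the AR(1) transform and beta1, beta2 and the
hyperparameters are updated by conjugate closed-form draws; rho moves by
random-walk Metropolis with reflection at the prior bounds (proposal scale
adapted during burn-in only); tau is drawn exactly from its discrete full
conditional each sweep, which avoids the poor mixing a random-walk update
of a change point exhibits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io import MIN_PHASE_LENGTH, ResultBundle, SCEDSeries, settings_hash

__all__ = [
    "BUCPParams",
    "BUCPPriors",
    "MCMCSettings",
    "BUCPPosterior",
    "log_likelihood",
    "tau_full_conditional",
    "tau_support",
    "sample_posterior",
    "precision_to_sd",
    "sd_to_precision",
    "split_rhat",
]

_LOG2PI = math.log(2.0 * math.pi)


def precision_to_sd(precision: float) -> float:
    """Convert a normal precision to the equivalent standard deviation."""
    if precision <= 0:
        raise ValueError("precision must be positive")
    return 1.0 / math.sqrt(precision)


def sd_to_precision(sd: float) -> float:
    if sd <= 0:
        raise ValueError("sd must be positive")
    return 1.0 / (sd * sd)


def tau_support(n: int) -> np.ndarray:
    """Admissible change-point values {3, ..., n-3} for a length-n series."""
    support = np.arange(MIN_PHASE_LENGTH, n - MIN_PHASE_LENGTH + 1)
    if support.size == 0:
        raise ValueError(f"series of length {n} admits no change point")
    return support


@dataclass(frozen=True)
class BUCPParams:
    """One point in parameter space (tau may be None for tau-marginal ops)."""

    beta1: float
    beta2: float
    rho: float
    sigma_eps: float
    tau: int | None = None

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not self.sigma_eps > 0:
            raise ValueError(f"sigma_eps must be > 0, got {self.sigma_eps}")

    @property
    def sigma_e(self) -> float:
        """Stationary marginal error SD sigma_eps / sqrt(1 - rho^2)."""
        return self.sigma_eps / math.sqrt(1.0 - self.rho * self.rho)


@dataclass(frozen=True)
class BUCPPriors:
    """Hyperparameters of the relatively uninformative default priors."""

    beta_hypermean_mean: float = 0.0
    beta_hypermean_precision: float = 1e-4  # SD 100
    beta_precision_shape: float = 1.0
    beta_precision_rate: float = 1.0
    rho_low: float = -1.0
    rho_high: float = 1.0
    error_precision_shape: float = 1.0
    error_precision_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "beta_hypermean_precision",
            "beta_precision_shape",
            "beta_precision_rate",
            "error_precision_shape",
            "error_precision_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1 <= self.rho_low < self.rho_high <= 1:
            raise ValueError("rho prior bounds must satisfy -1 <= low < high <= 1")

    @property
    def beta_hypermean_sd(self) -> float:
        return precision_to_sd(self.beta_hypermean_precision)

    def tau_prior(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Uniform prior over the admissible change points of a length-n series."""
        support = tau_support(n)
        return support, np.full(support.size, 1.0 / support.size)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler controls. Defaults give 4 x 10000 retained draws."""

    n_chains: int = 4
    n_adapt: int = 2000
    n_samples: int = 10000
    thin: int = 1
    seed: int = 0
    rho_proposal_sd: float = 0.1
    psrf_threshold: float = 1.1
    init_variance: str = "stationary"  # or "literal"
    fix_rho: float | None = None  # fix rho (oracle comparisons)
    fix_sigma_eps: float | None = None  # fix sigma_eps

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_samples, self.thin) < 1 or self.n_adapt < 0:
            raise ValueError("chain/sample counts must be positive")
        if self.rho_proposal_sd <= 0:
            raise ValueError("rho_proposal_sd must be positive")
        if self.init_variance not in ("stationary", "literal"):
            raise ValueError("init_variance must be 'stationary' or 'literal'")


# ---------------------------------------------------------------------------
# Likelihood


def _loglik(
    y: np.ndarray,
    beta1: float,
    beta2: float,
    rho: float,
    sigma_eps: float,
    tau: int,
    init_variance: str,
) -> float:
    n = y.size
    t = np.arange(1, n + 1)
    mu = np.where(t <= tau, beta1, beta2)
    s2 = sigma_eps * sigma_eps
    var1 = s2 / (1.0 - rho * rho) if init_variance == "stationary" else s2
    r0 = y[0] - mu[0]
    ll = -0.5 * (_LOG2PI + math.log(var1) + r0 * r0 / var1)
    r = y[1:] - mu[1:] - rho * (y[:-1] - mu[:-1])
    ll += -0.5 * ((n - 1) * (_LOG2PI + math.log(s2)) + float(r @ r) / s2)
    return float(ll)


def log_likelihood(
    series: SCEDSeries, params: BUCPParams, *, init_variance: str = "stationary"
) -> float:
    """Exact AR(1) log likelihood of the series under ``params``.

    The AR recursion runs uninterrupted across the change point: only the
    mean shifts at tau, never the error process.
    """
    if params.tau is None:
        raise ValueError("params.tau is required for log_likelihood")
    if init_variance not in ("stationary", "literal"):
        raise ValueError("init_variance must be 'stationary' or 'literal'")
    return _loglik(
        series.values,
        params.beta1,
        params.beta2,
        params.rho,
        params.sigma_eps,
        int(params.tau),
        init_variance,
    )


def _tau_log_weights(
    y: np.ndarray,
    beta1: float,
    beta2: float,
    rho: float,
    lam: float,
    support: np.ndarray,
    init_variance: str,
) -> np.ndarray:
    """Log p(y | tau=k, rest) over the support, up to a shared constant."""
    n = y.size
    t = np.arange(1, n + 1)[None, :]
    k = support[:, None]
    mu = np.where(t <= k, beta1, beta2)  # (K, n)
    r = (y[1:] - mu[:, 1:]) - rho * (y[:-1] - mu[:, :-1])
    ll = -0.5 * lam * np.einsum("ij,ij->i", r, r)
    # first-observation term (constant over k whenever min(support) >= 1)
    var1 = 1.0 / (lam * (1.0 - rho * rho)) if init_variance == "stationary" else 1.0 / lam
    r0 = y[0] - mu[:, 0]
    ll += -0.5 * r0 * r0 / var1
    return ll


def tau_full_conditional(
    series: SCEDSeries,
    params: BUCPParams,
    priors: BUCPPriors | None = None,
    *,
    init_variance: str = "stationary",
) -> tuple[np.ndarray, np.ndarray]:
    """Exact discrete full conditional p(tau = k | beta, rho, sigma_eps, y).

    Returns ``(support, probabilities)``; probabilities are normalised with a
    log-sum-exp guard and sum to one to ~1e-15.  ``params.tau`` is ignored.
    """
    priors = priors or BUCPPriors()
    support, prior = priors.tau_prior(series.n)
    logw = _tau_log_weights(
        series.values,
        params.beta1,
        params.beta2,
        params.rho,
        1.0 / params.sigma_eps**2,
        support,
        init_variance,
    ) + np.log(prior)
    probs = np.exp(logw - logsumexp(logw))
    return support, probs / probs.sum()


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class BUCPPosterior:
    """Joint posterior draws, shape (n_chains, n_samples) per parameter."""

    beta1: np.ndarray
    beta2: np.ndarray
    rho: np.ndarray
    sigma_eps: np.ndarray
    tau: np.ndarray
    priors: BUCPPriors
    settings: MCMCSettings
    series_label: str
    design_cp: int
    n: int
    rho_acceptance: tuple[float, ...] = ()
    warnings_: list[str] = field(default_factory=list)

    @property
    def sigma_e(self) -> np.ndarray:
        return self.sigma_eps / np.sqrt(1.0 - self.rho**2)

    def flat(self, name: str) -> np.ndarray:
        return np.asarray(getattr(self, name)).reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.beta1.size

    def rhat(self) -> dict[str, float]:
        """Split-Rhat (PSRF) per continuous parameter; NaN if fixed."""
        out = {}
        for name in ("beta1", "beta2", "rho", "sigma_eps"):
            draws = getattr(self, name)
            if np.ptp(draws) == 0:  # fixed or degenerate
                out[name] = float("nan")
            else:
                out[name] = split_rhat(draws)
        return out

    @property
    def converged(self) -> bool:
        vals = [v for v in self.rhat().values() if np.isfinite(v)]
        return all(v < self.settings.psrf_threshold for v in vals)

    def to_frame(self):
        """Raw draws, one row per retained draw."""
        import pandas as pd

        c, s = self.beta1.shape
        es = (self.beta2 - self.beta1) / self.sigma_eps
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), s),
                "iter": np.tile(np.arange(s), c),
                "beta1": self.flat("beta1"),
                "beta2": self.flat("beta2"),
                "rho": self.flat("rho"),
                "sigma_eps": self.flat("sigma_eps"),
                "tau": self.flat("tau"),
                "es": es.reshape(-1),
            }
        )

    def summary(self, mass: float = 0.95, standardizer: str = "innovation_sd"):
        """Posterior means with HDI bounds, one row per parameter."""
        import pandas as pd

        from .inference import effect_size_draws, hdi

        rows = []
        for name in ("beta1", "beta2", "rho", "sigma_eps"):
            draws = self.flat(name)
            lo, hi = hdi(draws, mass)
            rows.append(
                {"parameter": name, "estimate": draws.mean(), "lower": lo, "upper": hi}
            )
        taus = self.flat("tau")
        counts = np.bincount(taus, minlength=self.n)
        mode = int(np.argmax(counts))
        rows.append(
            {
                "parameter": "tau",
                "estimate": mode,
                "lower": int(taus.min()),
                "upper": int(taus.max()),
            }
        )
        es = effect_size_draws(self, standardizer).values
        lo, hi = hdi(es, mass)
        rows.append({"parameter": "es", "estimate": es.mean(), "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def to_bundle(self, mass: float = 0.95, standardizer: str = "innovation_sd") -> ResultBundle:
        rows = self.summary(mass, standardizer).to_dict("records")
        return ResultBundle(
            series_label=self.series_label,
            method="bucp",
            rows=rows,
            provenance={
                "seed": self.settings.seed,
                "settings_hash": settings_hash(self.settings, self.priors),
                "converged": self.converged,
                "standardizer": standardizer,
            },
        )


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction factor with chains split in half (BDA3)."""
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    c, s = x.shape
    half = s // 2
    if half < 2:
        return float("nan")
    x = x[:, : 2 * half].reshape(2 * c, half)
    within = x.var(axis=1, ddof=1).mean()
    between = half * x.mean(axis=1).var(ddof=1)
    if within == 0:
        return float("nan")
    var_hat = (half - 1) / half * within + between / half
    return float(math.sqrt(var_hat / within))


# ---------------------------------------------------------------------------
# Sampler


def _reflect(x: float, lo: float, hi: float) -> float:
    for _ in range(100):
        if lo < x < hi:
            return x
        if x <= lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
    return min(max(x, lo + 1e-12), hi - 1e-12)


def _run_chain(
    y: np.ndarray,
    design_cp: int,
    priors: BUCPPriors,
    settings: MCMCSettings,
    seed_seq: np.random.SeedSequence,
) -> dict:
    rng = np.random.default_rng(seed_seq)
    n = y.size
    support = tau_support(n)
    stationary = settings.init_variance == "stationary"

    p0 = priors.beta_hypermean_precision
    mu0 = priors.beta_hypermean_mean
    h_shape, h_rate = priors.beta_precision_shape, priors.beta_precision_rate
    e_shape, e_rate = priors.error_precision_shape, priors.error_precision_rate
    rho_lo, rho_hi = priors.rho_low, priors.rho_high

    # data-based starting point
    tau = int(np.clip(design_cp - 1, support[0], support[-1]))
    b1 = float(y[:tau].mean())
    b2 = float(y[tau:].mean())
    mu_init = np.where(np.arange(1, n + 1) <= tau, b1, b2)
    resid_var = max(float(np.var(y - mu_init)), 1e-8)
    fixed_lam = settings.fix_sigma_eps is not None
    lam = 1.0 / settings.fix_sigma_eps**2 if fixed_lam else 1.0 / resid_var
    fixed_rho = settings.fix_rho is not None
    rho = float(settings.fix_rho) if fixed_rho else 0.0
    if fixed_rho and not rho_lo < rho < rho_hi:
        raise ValueError("fix_rho outside the prior bounds")
    m = 0.5 * (b1 + b2)
    h = 1.0

    n_keep = settings.n_samples
    total = settings.n_adapt + n_keep * settings.thin
    out = {
        k: np.empty(n_keep) for k in ("beta1", "beta2", "rho", "sigma_eps")
    }
    out["tau"] = np.empty(n_keep, dtype=int)

    prop_sd = settings.rho_proposal_sd
    acc = tries = 0
    win_acc = win_tries = 0
    cur_ll = None  # cached log likelihood for the rho update

    idx = 0
    for it in range(total):
        adapting = it < settings.n_adapt

        # --- conjugate block: whiten given (rho, tau), draw beta | rest
        a = 1.0 - rho
        s1sq = 1.0 - rho * rho if stationary else 1.0
        yt = y[1:] - rho * y[:-1]  # t = 2..n
        c11 = s1sq + (tau - 1) * a * a + rho * rho
        c12 = -rho
        c22 = 1.0 + (n - tau - 1) * a * a
        v1 = s1sq * y[0] + a * float(yt[: tau - 1].sum()) - rho * yt[tau - 1]
        v2 = yt[tau - 1] + a * float(yt[tau:].sum())

        p11 = lam * c11 + h
        p12 = lam * c12
        p22 = lam * c22 + h
        q1 = lam * v1 + h * m
        q2 = lam * v2 + h * m
        det = p11 * p22 - p12 * p12
        mean1 = (p22 * q1 - p12 * q2) / det
        mean2 = (p11 * q2 - p12 * q1) / det
        # draw from N(mean, P^{-1}) via the Cholesky of the precision
        l11 = math.sqrt(p11)
        l21 = p12 / l11
        l22 = math.sqrt(p22 - l21 * l21)
        z1, z2 = rng.standard_normal(2)
        # solve L^T x = z
        x2 = z2 / l22
        x1 = (z1 - l21 * x2) / l11
        b1 = mean1 + x1
        b2 = mean2 + x2

        # --- hypermean m and hyperprecision h
        prec_m = p0 + 2.0 * h
        mean_m = (p0 * mu0 + h * (b1 + b2)) / prec_m
        m = mean_m + rng.standard_normal() / math.sqrt(prec_m)
        ss_b = (b1 - m) ** 2 + (b2 - m) ** 2
        h = rng.gamma(h_shape + 1.0, 1.0 / (h_rate + 0.5 * ss_b))

        # --- error precision
        if not fixed_lam:
            r0 = math.sqrt(s1sq) * (y[0] - b1)
            rA = yt[: tau - 1] - a * b1
            rC = yt[tau - 1] + rho * b1 - b2
            rB = yt[tau:] - a * b2
            ssr = r0 * r0 + float(rA @ rA) + rC * rC + float(rB @ rB)
            lam = rng.gamma(e_shape + 0.5 * n, 1.0 / (e_rate + 0.5 * ssr))

        sigma = 1.0 / math.sqrt(lam)

        # --- rho: random-walk Metropolis with reflection at the prior bounds
        if not fixed_rho:
            cur_ll = _loglik(y, b1, b2, rho, sigma, tau, settings.init_variance)
            prop = _reflect(rho + prop_sd * rng.standard_normal(), rho_lo, rho_hi)
            new_ll = _loglik(y, b1, b2, prop, sigma, tau, settings.init_variance)
            tries += 1
            win_tries += 1
            if math.log(rng.random()) < new_ll - cur_ll:
                rho = prop
                acc += 1
                win_acc += 1
            if adapting and win_tries == 50:
                # target 20-50% acceptance; frozen once burn-in ends
                rate = win_acc / win_tries
                if rate < 0.2:
                    prop_sd *= 0.7
                elif rate > 0.5:
                    prop_sd *= 1.4
                win_acc = win_tries = 0
        else:
            rng.standard_normal()  # keep the stream aligned across fix modes
            rng.random()

        # --- tau: exact categorical Gibbs
        logw = _tau_log_weights(y, b1, b2, rho, lam, support, settings.init_variance)
        logw -= logw.max()
        w = np.exp(logw)
        cdf = np.cumsum(w)
        tau = int(support[np.searchsorted(cdf, rng.random() * cdf[-1])])

        if not adapting and (it - settings.n_adapt) % settings.thin == 0:
            out["beta1"][idx] = b1
            out["beta2"][idx] = b2
            out["rho"][idx] = rho
            out["sigma_eps"][idx] = sigma
            out["tau"][idx] = tau
            idx += 1

    out["rho_acceptance"] = acc / tries if tries else float("nan")
    return out


def sample_posterior(
    series: SCEDSeries,
    priors: BUCPPriors | None = None,
    settings: MCMCSettings | None = None,
) -> BUCPPosterior:
    """Draw from the joint BUCP posterior by Metropolis-within-Gibbs.

    Bit-reproducible given (seed, settings, priors, series); per-chain seeds
    are spawned deterministically from the master seed.  Non-convergence
    (any split-Rhat >= the threshold) produces a warning carried on the
    posterior object, never an exception.
    """
    priors = priors or BUCPPriors()
    settings = settings or MCMCSettings()
    master = np.random.SeedSequence(settings.seed)
    chains = [
        _run_chain(series.values, series.design_cp, priors, settings, child)
        for child in master.spawn(settings.n_chains)
    ]
    post = BUCPPosterior(
        beta1=np.stack([c["beta1"] for c in chains]),
        beta2=np.stack([c["beta2"] for c in chains]),
        rho=np.stack([c["rho"] for c in chains]),
        sigma_eps=np.stack([c["sigma_eps"] for c in chains]),
        tau=np.stack([c["tau"] for c in chains]),
        priors=priors,
        settings=settings,
        series_label=series.label,
        design_cp=series.design_cp,
        n=series.n,
        rho_acceptance=tuple(c["rho_acceptance"] for c in chains),
    )
    bad = {k: v for k, v in post.rhat().items() if np.isfinite(v) and v >= settings.psrf_threshold}
    if bad:
        msg = "PSRF above threshold: " + ", ".join(f"{k}={v:.3f}" for k, v in bad.items())
        post.warnings_.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return post
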