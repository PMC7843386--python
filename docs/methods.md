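# Methods

## Model

A two-phase single-case series y_1..y_n is modelled as a piecewise-constant
mean with a continuous AR(1) error process:

* mean: μ_t = β₀₁ for t ≤ τ, β₀₂ for t > τ, where the change point τ is the
  last time point governed by the baseline intercept;
* errors: e_t = ρ e_{t−1} + ε_t, ε_t ~ N(0, σ_ε²), |ρ| < 1. The error
  process never resets at τ: a delayed onset shifts only the mean.

The likelihood is evaluated sequentially: y_t | y_{t−1} ~
N(μ_t + ρ(y_{t−1} − μ_{t−1}), σ_ε²) for t ≥ 2. For the first observation we
use the stationary marginal N(μ_1, σ_e²) with σ_e = σ_ε/√(1 − ρ²), so the
joint density equals the n-dimensional Gaussian with covariance
σ_e² ρ^|i−j|. `init_variance="literal"` instead uses σ_ε² for y_1 — a
non-stationary initialisation some formulations write; the default is the
stationary one because σ_e is defined as the marginal scale. The difference
is one likelihood term and is negligible except at very small n with |ρ|
near 1.

There are no slope/trend terms, no multiple change points, and no
count/proportion likelihoods: the model targets level change in continuous,
normally distributed outcomes. Real SCED outcomes are often counts or
percentages; users should judge whether a normal approximation is tolerable
at their scale.

## Priors

All defaults are deliberately weak; every hyperparameter is a field of
`BUCPPriors`:

| parameter | prior | default | note |
|---|---|---|---|
| β₀₁, β₀₂ | N(m, 1/h) | — | common hypermean/hyperprecision |
| m | N(0, precision 1e−4) | SD 100 | outcome units |
| h | Gamma(shape 1, rate 1) | mean 1 | precision of the β's around m |
| ρ | Uniform(−1, 1) | — | full stationary range |
| 1/σ_ε² | Gamma(shape 1, rate 1) | mean 1 | no scale prior is standard for SCEDs; Gamma(1,1) on the precision is this package's choice and should be tightened when the outcome scale is known |
| τ | uniform on {3, …, n−3} | — | ≥ 3 observations per phase |

With series of 6–40 points the β and τ posteriors are data-dominated; the
σ_ε prior is the one that matters most at very small n.

## Sampler

Metropolis-within-Gibbs, one sweep =

1. **β₀₁, β₀₂** — conditional on (ρ, σ_ε, τ), the series is whitened by the
   AR(1) transform (first row scaled by √(1 − ρ²), then ỹ_t = y_t − ρ
   y_{t−1}); the whitened model is linear-Gaussian, so the intercepts are
   drawn from their exact bivariate normal conditional.
2. **m, h** — conjugate normal and gamma updates given the β's.
3. **1/σ_ε²** — conjugate gamma update from the whitened residuals.
4. **ρ** — random-walk Metropolis on (−1, 1) with reflection at the bounds;
   the proposal SD (default 0.1) is adapted toward 20–50% acceptance during
   burn-in only, so the retained chain is a valid Markov chain.
5. **τ** — exact categorical draw from its discrete full conditional,
   computed over the whole support with a log-sum-exp guard. This is the
   step that makes the change point mix essentially perfectly, where a
   random-walk update would crawl.

Defaults: 4 chains, 2000 adaptation + 10000 retained draws per chain,
thin 1, one master seed with per-chain seeds spawned deterministically
(bit-reproducible reruns). Convergence is monitored by split-R̂ (PSRF) on
the continuous parameters; values ≥ 1.1 produce a warning carried on the
posterior object, never an exception. The replicate studies in
`sced.studies` use 2 chains × (400 + 1100) draws: with these short,
strongly informative series the posterior is simple, and across 100
replicates the mode/coverage estimates are insensitive to chain length well
below the asserted margins.

Ties in the τ posterior mode are resolved to the smallest index and flagged
as multimodal; a multimodal or diffuse posterior yields the `unclear`
immediacy verdict.

## Decision quantities

* **HDI** — narrowest contiguous window containing ⌈mass·n⌉ sorted draws
  (leftmost window on ties; ≥ 100 draws required). For the discrete τ a
  highest-mass *set* is used instead, since the discrete posterior need not
  be contiguous.
* **Effect size** — ES = (β₀₂ − β₀₁)/σ_ε per draw, sign preserved. The
  innovation SD is the default standardizer; σ_e (marginal) is available
  and is always ≤ in magnitude. No consensus denominator exists for this
  within-subject ES, and it cannot be aggregated across studies
  meta-analytically; the choice is recorded in the output provenance.
* **Immediacy** — `immediate` if the τ mode equals design change-point − 1
  with ≥ 50% of posterior mass on the mode (the mass rule is this package's
  operational proxy for "concentrated posterior"; 0.5 guarantees a unique
  majority mode and is configurable); `delayed` if a dominant mode falls
  later; `unclear` otherwise, including modes *before* the intervention.
* **ROPE** — `accept_effect` iff the 95% HDI lower bound ≥ threshold
  (default 3, inclusive); `accept_null` iff the HDI lies inside the null
  region (default (−threshold, threshold)); else `undecided`.

## SMA

`estimate_lag1` centres each phase at its own mean and computes the
lagged-pairs Pearson correlation of residual_t with residual_{t−1}, clipped
to (−0.99, 0.99). Phase-centring keeps a genuine level shift from inflating
the autocorrelation estimate.

Two small-sample facts shape the defaults. First, the phase-centred
estimator is biased down by ≈ 2(1 + 3ρ)/n (one Kendall-type (1 + 3ρ)/n term
per fitted phase mean); `bias_correct=True` (default) inverts this:
ρ̂ = (r + 2/n)/(1 − 6/n). Second, even after mean-bias correction the
estimate is noisy (SD ≈ 0.3 at n = 20), and a null distribution built at a
single plugged-in ρ̂ is anti-conservative because the rejection probability
is convex in the estimation error. `rho_uncertainty=True` (default)
therefore draws each surrogate's lag-1 coefficient from
N(ρ̂, Bartlett SD × bias-inversion factor), truncated to the stationary
region — a predictive null that propagates the nuisance uncertainty.
Measured on null AR(1) series (10+10 points, 500 replicates): the naive
plug-in test rejects at 0.078 (ρ = 0) and 0.118 (ρ = 0.3) at α = 0.05; the
default test rejects at 0.04–0.06 for both. Setting both flags to False
restores the naive behaviour.

Surrogates are zero-mean unit-variance Gaussian AR(1) with no phase effect;
Pearson r is affine-invariant, so matching the observed location/scale is
unnecessary. p = (#{|r_sim| ≥ |r_obs|} + 1)/(n_sim + 1) (two-tailed default;
one-tailed compares signed r), so p is never 0 and has resolution
1/(n_sim + 1). Shipped contrasts: `level` (phase dummy), `ramp_b` (0 in A,
linear ramp within B), `linear_trend`, `b_decay` (1→0 within B). Running
several contrasts inflates the experiment-wise type-I error; the output
labels each vector and reports the number of tests, and no correction is
applied — matching how such tools are used in practice.

τ/latency is deliberately *not* modelled in SMA: its inability to represent
delayed onsets is the behaviour the BUCP comparison is designed to expose.

## Synthetic data

`simulate_sced` draws exactly from the model above (stationary first point,
continuous AR process across the change), with the true change point at
n_a + latency. Presets:

* `clear` — 15+15 points, step 5σ_ε, ρ = 0.2, latency 0;
* `delayed` — 8+9 points, step 10σ_ε, ρ = 0.2, latency 3 (true τ = 11,
  design change-point 9);
* `unclear` — 7+16 points, step 1.5σ_ε at σ_ε = 2, ρ = 0.2, latency drawn
  uniformly from the middle third of phase B.

Because generator and likelihood share one stochastic law, recovery and
coverage results validate the *inference machinery*, not the model's
adequacy for any real behavioural outcome: real series may have trends,
bounded/count scales, or non-AR(1) dependence, none of which the generator
emulates. Truth records are written to a sidecar JSON, never parsed back
out of the series file.

## Verification

* the exact AR(1) likelihood is tested against a dense-covariance
  multivariate-normal evaluation; the τ full conditional against brute-force
  enumeration;
* the sampler's τ marginal (ρ, σ_ε fixed at truth) is compared with an
  exact enumeration that integrates the intercept hierarchy analytically
  (per-candidate Gaussian marginal + quadrature over the β-precision
  prior) — total-variation distance ≈ 0.003 at 50,000 draws;
* full-prior simulation-based calibration (draw parameters from the prior,
  simulate, refit, rank the truth among thinned draws) yields uniform ranks
  for β₀₁, β₀₂, ρ and σ_ε;
* replicate studies: change-point recovery and HDI coverage on `clear`,
  the BUCP-detects/SMA-misses contrast on `delayed`, and type-I calibration
  of the surrogate test — all recomputed by `scripts/acceptance.py`.

Problem sizes in the shipped studies (100 analysis replicates, 500
calibration replicates, 2000–50000 Monte-Carlo draws) were chosen so the
binomial/Monte-Carlo error of each reported rate is well inside the margin
being asserted.

## Known limitations

* Level change only; a real trend will be absorbed into ρ and the
  intercepts, and can bias the change-point posterior.
* One series at a time; multiple-baseline designs are analysed per subject
  with no cross-subject pooling.
* The ES threshold 3 is an illustrative convention, not a clinical
  constant; set it per outcome.
* The SMA ρ̂-uncertainty null uses a normal approximation to the
  estimator's sampling distribution; at |ρ̂| near 1 truncation makes it
  conservative.
* Equally spaced observations are assumed; files with time gaps are
  rejected rather than imputed.
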