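"""Synthetic two-phase SCED series with known ground truth.

The generator draws exactly from the model the BUCP likelihood assumes —
a piecewise-constant mean with continuous AR(1) errors — so parameter
recovery and calibration studies have an unambiguous truth.  Real SCED
outcomes are often counts or percentages; the generator deliberately
matches the continuous-normal model rather than those raw data types.

Three presets mirror the qualitative regimes seen in applied series:

* ``clear``   — immediate large step (5 sigma) at the intervention point.
* ``delayed`` — large step (10 sigma) but only 3 points after the
  intervention starts, on short 8+9 phases.
* ``unclear`` — modest step (1.5 sigma) with higher noise and a latency
  drawn from the middle third of the intervention phase, so the onset is
  genuinely ambiguous.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import MIN_PHASE_LENGTH, SCEDSeries, save_series

__all__ = ["SimScenario", "simulate_sced", "preset", "PRESETS"]


@dataclass(frozen=True)
class SimScenario:
    """Generator parameters for one synthetic series.

    ``latency`` is the number of post-intervention points still generated
    at the baseline mean, so the true change point is ``n_a + latency``
    (0 = clear immediacy).
    """

    n_a: int
    n_b: int
    beta1: float
    beta2: float
    sigma_eps: float = 1.0
    rho: float = 0.0
    latency: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_a < MIN_PHASE_LENGTH or self.n_b < MIN_PHASE_LENGTH:
            raise ValueError(f"phases need >= {MIN_PHASE_LENGTH} points each")
        if not 0 <= self.latency <= self.n_b - MIN_PHASE_LENGTH:
            raise ValueError(
                f"latency must be in [0, n_b - {MIN_PHASE_LENGTH}] so at least "
                f"{MIN_PHASE_LENGTH} points sit past the true change point"
            )
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")

    @property
    def n(self) -> int:
        return self.n_a + self.n_b

    @property
    def true_tau(self) -> int:
        """Last time point generated at the baseline mean."""
        return self.n_a + self.latency

    @property
    def design_cp(self) -> int:
        return self.n_a + 1


def simulate_sced(
    scenario: SimScenario, seed: int | np.random.Generator | None = None
) -> tuple[SCEDSeries, dict]:
    """Generate one series plus its ground-truth record.

    y_1 ~ Normal(beta1, sigma_e^2) with the stationary marginal SD
    sigma_e = sigma_eps / sqrt(1 - rho^2); for t >= 2,
    y_t = mu_t + rho (y_{t-1} - mu_{t-1}) + eps_t with mu switching from
    beta1 to beta2 after the true change point.  The AR process never
    resets: a delayed onset shifts only the mean. Bit-reproducible per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scenario.n
    tau = scenario.true_tau
    t = np.arange(1, n + 1)
    mu = np.where(t <= tau, scenario.beta1, scenario.beta2)
    sigma_e = scenario.sigma_eps / np.sqrt(1.0 - scenario.rho**2)
    y = np.empty(n)
    y[0] = mu[0] + sigma_e * rng.standard_normal()
    eps = scenario.sigma_eps * rng.standard_normal(n - 1)
    for i in range(1, n):
        y[i] = mu[i] + scenario.rho * (y[i - 1] - mu[i - 1]) + eps[i - 1]
    series = SCEDSeries(values=y, design_cp=scenario.design_cp, label=scenario.label)
    truth = dict(asdict(scenario), true_tau=tau, design_cp=scenario.design_cp)
    return series, truth


#: Preset scenario builders (callables of an optional rng, for the drawn
#: latency of the ``unclear`` regime).
PRESETS = ("clear", "delayed", "unclear")


def preset(
    name: str, seed: int | np.random.Generator | None = None, **overrides
) -> SimScenario:
    """Build a preset scenario; ``overrides`` replace individual fields."""
    if name == "clear":
        base = dict(
            n_a=15, n_b=15, beta1=0.0, beta2=5.0, sigma_eps=1.0, rho=0.2, latency=0
        )
    elif name == "delayed":
        base = dict(
            n_a=8, n_b=9, beta1=0.0, beta2=10.0, sigma_eps=1.0, rho=0.2, latency=3
        )
    elif name == "unclear":
        base = dict(
            n_a=7, n_b=16, beta1=0.0, beta2=3.0, sigma_eps=2.0, rho=0.2
        )
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_b = int(overrides.get("n_b", base["n_b"]))
        lo, hi = n_b // 3, min(2 * n_b // 3, n_b - MIN_PHASE_LENGTH)
        base["latency"] = int(rng.integers(lo, hi + 1))
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    base["label"] = name
    base.update(overrides)
    return SimScenario(**base)


def write_simulation(
    scenario: SimScenario, seed: int | None, out_csv: str | Path
) -> tuple[Path, Path]:
    """Write the series CSV plus a truth-record sidecar JSON."""
    series, truth = simulate_sced(scenario, seed)
    out_csv = Path(out_csv)
    save_series(series, out_csv)
    truth_path = out_csv.with_suffix(".truth.json")
    truth["seed"] = seed
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out_csv, truth_path
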