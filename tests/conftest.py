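import numpy as np
import pytest

from sced import SCEDSeries, SimScenario, simulate_sced


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def step_series():
    """Deterministic 6+6 series with a clean level step at tau = 6."""
    y = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.0, 5.0, 5.2, 4.8, 5.1, 4.9, 5.0])
    return SCEDSeries(values=y, design_cp=7, label="step")


@pytest.fixture
def noisy_series():
    """AR(1) series from the generator with a 3-sigma step, 10+10 points."""
    scen = SimScenario(
        n_a=10, n_b=10, beta1=0.0, beta2=3.0, sigma_eps=1.0, rho=0.3, latency=0
    )
    series, _ = simulate_sced(scen, 42)
    return series
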