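import numpy as np
import pytest

from extrigger import AbundanceSeries, RunConfig, ScenarioSpec, generate


@pytest.fixture
def exact_line() -> AbundanceSeries:
    """Noiseless decline N_t = 100 - 5 t over 9 years."""
    t = np.arange(9)
    return AbundanceSeries(2000 + t, 100.0 - 5.0 * t)


@pytest.fixture
def steady_series() -> AbundanceSeries:
    """Long noiseless steady decline used by the replay tests."""
    return generate(ScenarioSpec("steady", n0=100.0, slope=-5.0, noise_sd=0.0,
                                 n_years=20))


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig()
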