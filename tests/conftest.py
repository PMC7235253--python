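import numpy as np
import pytest

from hippotheta.synthdata import ElectrodeSpec, SimConfig, simulate_behavior


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A short-but-realistic task configuration (12 trials, ~190 s)."""
    return SimConfig(n_trials=12, seed=0)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return simulate_behavior(small_config, np.random.default_rng(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def high_spec():
    return ElectrodeSpec([(7.0, 9.0)], speed_coupled=True)


@pytest.fixture(scope="session")
def dual_spec():
    return ElectrodeSpec([(2.3, 3.7), (7.0, 9.0)], speed_coupled=[False, True])
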