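import numpy as np
import pytest

from pupilcode import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.SimulationConfig:
    """A short session that still exercises every generator component."""
    return syn.SimulationConfig(duration_s=600.0, n_rewards=6, n_cells=12, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config) -> syn.Session:
    return syn.simulate_session(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
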