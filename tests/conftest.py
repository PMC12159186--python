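import numpy as np
import pytest

from riftsearch import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale experiment: all four condition cells, planted effects."""
    return SimConfig(n_blocks=8, trials_per_block=12, snr=0.5,
                     search_duration=0.8, n_sensors=6,
                     signal_sensors=(0, 1, 2), seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    rec, trials, layouts, gazes = generate_experiment(small_config)
    return rec, trials, layouts, gazes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
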