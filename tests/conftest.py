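import numpy as np
import pytest

from mrspeaks import SimulationConfig, synthesize_spectrum


@pytest.fixture
def quiet_config():
    """Noise-free synthesis config with flat zero baseline."""
    return SimulationConfig(noise_sd=0.0)


@pytest.fixture
def default_heights():
    return {"naa": 8.0, "cr": 4.0, "tcho": 6.0, "mins": 5.0,
            "lmm09": 2.0, "lmm13": 3.0}


@pytest.fixture
def typical_spectrum(default_heights):
    """A realistic synthetic spectrum: known heights, mild noise."""
    config = SimulationConfig(noise_sd=0.05)
    return synthesize_spectrum(default_heights, config, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20180730)
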