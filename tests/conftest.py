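import numpy as np
import pytest

from pondcast import SyntheticConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_frame():
    """Fault-free, noise-free frame: every sensor reads the truth exactly."""
    cfg = SyntheticConfig(
        n_samples=144, seed=7, noise_sd=0.0, zero_fault_rate=0.0,
        spike_fault_rate=0.0, biased_sensor_index=None, bias_offset=0.0,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def faulty_frame():
    """Frame with the default fault mix (zeros, spikes, one biased sensor)."""
    return simulate(SyntheticConfig(n_samples=700, seed=11))
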