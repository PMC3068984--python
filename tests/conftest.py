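import numpy as np
import pytest

from srsleep.simulate import SimConfig, default_presets


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture
def sim_config():
    return SimConfig(seed=12345)


@pytest.fixture
def short_config():
    """One-hour recording (900 epochs) for signal-level tests."""
    return SimConfig(n_days=1, recording_hours=1.0, seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def random_hypnogram(rng, n=500, zt_start=0.0, p=(0.45, 0.45, 0.10)):
    from srsleep.states import Hypnogram

    return Hypnogram(states=rng.choice(3, size=n, p=p).astype(np.int8), zt_start=zt_start)
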