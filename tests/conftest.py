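import numpy as np
import pytest

from pairbond.synthetic import SimConfig


@pytest.fixture
def sim() -> SimConfig:
    """Default-condition generator config with a fixed seed."""
    return SimConfig(seed=7)


@pytest.fixture
def quick_sim() -> SimConfig:
    """Short sessions / cheap sweeps for fast unit tests."""
    return SimConfig(
        seed=7,
        session_length_s=120.0,
        spontaneous_duration_s=10.0,
        fs_ephys=5000.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
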