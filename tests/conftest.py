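import numpy as np
import pytest

from saccost.simulate import CostProfile, SimulationConfig


@pytest.fixture(scope="session")
def profile() -> CostProfile:
    """Anisotropy profile used throughout: oblique 0.3, down 0.1, left 0.05."""
    return CostProfile(c0=0.0, c_obl=0.3, c_down=0.1, c_left=0.05)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A single short session for unit-level pipeline tests."""
    return SimulationConfig(n_participants=1, n_sessions=1, trials_per_session=30, seed=7)


@pytest.fixture(scope="session")
def clean_config(small_config) -> SimulationConfig:
    """Noise-free, blink-free variant of the small session."""
    return small_config.replace(noise_sd=0.0, blink_rate=0.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
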