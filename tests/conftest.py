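import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xistlink import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config() -> SimulationConfig:
    """A small but fully featured simulation config for fast tests."""
    return SimulationConfig(seed=7, n_cells_per_genotype=20)


@pytest.fixture
def clean_config() -> SimulationConfig:
    """Noise-free config: no localization error, no merging, no contacts."""
    return SimulationConfig(
        seed=11,
        n_cells_per_genotype=20,
        localization_noise_sd=0.0,
        resolvability_threshold=0.0,
        contact_probability=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
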