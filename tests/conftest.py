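import numpy as np
import pytest

from osteomap import SimulationConfig, make_template, simulate_dataset


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy factorial dataset shared by read-only tests."""
    cfg = SimulationConfig(n_per_cell=2, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise, fully observed dataset: specimens equal their cell means."""
    cfg = SimulationConfig(n_per_cell=2, seed=7, landmark_noise_sd=0.0,
                           missing_landmark_rate=0.0)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
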