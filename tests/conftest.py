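import numpy as np
import pytest

from meaburst.simulate import SimConfig, generate_training_dataset, generate_well


@pytest.fixture(scope="session")
def small_well():
    """A short 12-channel simulated well with ground truth."""
    config = SimConfig(seed=42, duration_s=120.0)
    trains, truth = generate_well(config)
    return config, trains, truth


@pytest.fixture(scope="session")
def training_samples():
    """A small training dataset shared by model tests."""
    return generate_training_dataset(60, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
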