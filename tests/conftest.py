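import numpy as np
import pytest

from ddlibs.dataset import SpectraDataset
from ddlibs.synthetic import SimulationConfig, clean_config, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """3 wavelengths x 2 samples, hand-written."""
    return SpectraDataset(
        wavelengths=np.array([500.0, 501.0, 502.0]),
        intensities=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        sample_ids=["a", "b"],
        concentrations=np.array([0.5, 0.7]),
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, shift-free 90-sample dataset at full 512-point geometry."""
    return simulate_dataset(90, clean_config(seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    """Reduced 128-point grid for fast pipeline tests (supports 4 scales)."""
    return clean_config(seed=3, n_points=128)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(40, tiny_config)
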