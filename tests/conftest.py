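import numpy as np
import pytest

from tcncall.model import ModelConfig, TCNModel
from tcncall.simulate import DwellModel, generate_pore_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pore_k1():
    return generate_pore_model(1, seed=11)


@pytest.fixture(scope="session")
def pore_k3():
    return generate_pore_model(3, seed=42)


@pytest.fixture
def fixed_dwell8():
    return DwellModel(mean_dwell=8.0, distribution="fixed", min_dwell=1)


@pytest.fixture
def tiny_model():
    """A very small network for probe tests: full structure, few parameters."""
    cfg = ModelConfig(n_blocks=2, dilations=(1, 2), n_filters=8, fc1_channels=8)
    return TCNModel(cfg, seed=3)


def random_row_stochastic(rng: np.random.Generator, T: int) -> np.ndarray:
    O = rng.random((T, 5)) + 1e-3
    return O / O.sum(axis=1, keepdims=True)
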