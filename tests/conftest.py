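import numpy as np
import pytest

from clonecomp import ModelConfig


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def rho_dense_grid() -> np.ndarray:
    """Dense rho grid for forward/inverse round-trip checks."""
    return np.linspace(0.01, 1.0, 397)
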