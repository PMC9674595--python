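import numpy as np
import pytest

from hncsim import ModelParams


@pytest.fixture(scope="session")
def nc_params() -> ModelParams:
    """Pure neutral competition: drift only."""
    return ModelParams(K=10, N=100, epsilon=0.0, lam=1.0)


@pytest.fixture(scope="session")
def hier_params() -> ModelParams:
    """Purely hierarchical: master-cell supply only."""
    return ModelParams(K=10, N=100, epsilon=0.1, lam=0.0)


@pytest.fixture(scope="session")
def hnc_params() -> ModelParams:
    """Supply plus competition, low-supply (bursty) regime."""
    return ModelParams(K=10, N=100, epsilon=0.1, lam=1.0)


@pytest.fixture(scope="session")
def hema_params() -> ModelParams:
    """Primate-hematopoiesis-scale parameters."""
    return ModelParams(K=420, N=1000, epsilon=0.05, lam=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
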