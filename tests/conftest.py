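import numpy as np
import pytest

from isingnet.model import EstimationConfig
from isingnet.network import IsingNetwork
from isingnet.simulate import gibbs_sample, sparse_recovery_network


def random_binary(seed: int, n: int, p: int, q: float = 0.4) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return (rng.random((n, p)) < q).astype(np.int8)


@pytest.fixture(scope="session")
def net4() -> IsingNetwork:
    """Small chain-like 4-node network with one negative coupling."""
    omega = np.array(
        [
            [0.0, 0.8, 0.0, 0.0],
            [0.8, 0.0, -0.5, 0.0],
            [0.0, -0.5, 0.0, 0.6],
            [0.0, 0.0, 0.6, 0.0],
        ]
    )
    return IsingNetwork(np.array([0.2, -0.3, 0.1, 0.0]), omega)


@pytest.fixture(scope="session")
def net10() -> IsingNetwork:
    return sparse_recovery_network()


@pytest.fixture(scope="session")
def data4(net4):
    return gibbs_sample(net4, 400, seed=9)


@pytest.fixture(scope="session")
def data10(net10):
    return gibbs_sample(net10, 800, seed=21)


@pytest.fixture(scope="session")
def fast_config() -> EstimationConfig:
    """Shorter penalty path for tests that refit many times."""
    return EstimationConfig(n_lambda=30)
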