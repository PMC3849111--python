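import numpy as np
import pytest

from dendrogap.fixtures import (
    passive_dendrite,
    resonant_dendrite,
    two_cell_hetero_config,
    two_cell_identical_config,
    two_cell_network_config,
    two_soma_config,
    two_soma_network_config,
)
from dendrogap.network_model import build_network


@pytest.fixture(scope="session")
def res_params():
    return resonant_dendrite()


@pytest.fixture(scope="session")
def pas_params():
    return passive_dendrite()


@pytest.fixture(scope="session")
def identical_cfg():
    return two_cell_identical_config()


@pytest.fixture(scope="session")
def identical_net(identical_cfg):
    return build_network(two_cell_network_config(identical_cfg))


@pytest.fixture(scope="session")
def hetero_cfg():
    return two_cell_hetero_config()


@pytest.fixture(scope="session")
def hetero_net(hetero_cfg):
    return build_network(two_cell_network_config(hetero_cfg))


@pytest.fixture(scope="session")
def passive_cfg():
    return two_cell_identical_config(resonant=False)


@pytest.fixture(scope="session")
def soma_cfg():
    return two_soma_config(L_GJ=100.0, R_GJ=100.0)


@pytest.fixture(scope="session")
def soma_net(soma_cfg):
    return build_network(two_soma_network_config(soma_cfg))


def random_omegas(seed: int, n: int, re=(0.05, 3.0), im=(-2.0, 2.0)) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(*re, n) + 1j * rng.uniform(*im, n)


#: segment name -> live branch id in the two-cell network configs
TWO_CELL_SEGMENTS = {
    "m-": "cell_m:minus",
    "m+": "cell_m:plus",
    "n-": "cell_n:minus",
    "n+": "cell_n:plus",
}
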