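import numpy as np
import pytest

from critnet.network import build_network
from critnet.params import (DriveParams, NetworkConfig, NeuronParams,
                            WeightDist)


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def small_config():
    return NetworkConfig(N_exc=40, N_inh=10, k_EE=5, k_EI=2, k_IE=5, k_II=2,
                         seed=11)


@pytest.fixture(scope="session")
def small_net(small_config):
    return build_network(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
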