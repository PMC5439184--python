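import numpy as np
import pytest

from famnet import (NetworkConfig, Network, Simulation, build_input_projection,
                    build_network)


@pytest.fixture(scope="session")
def small_config():
    return NetworkConfig(dims=(6, 6, 3), lambda_=2.0, wscale=0.9, sh_w=0.25,
                         seed=7)


@pytest.fixture(scope="session")
def small_network(small_config):
    net = build_network(small_config)
    net.input_projection = build_input_projection(net, (6, 6))
    return net


@pytest.fixture()
def two_neuron_network():
    return Network(positions=np.array([[0, 0, 0], [1, 0, 0]]),
                   is_excitatory=np.array([True, True]),
                   pre=np.array([0]), post=np.array([1]),
                   weight=np.array([3e-8]))
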