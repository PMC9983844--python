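import numpy as np
import pytest

from resonet.network import ThresholdNetwork, build_network, sample_out_degrees


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_net(n, gamma, seed):
    g = np.random.default_rng(seed)
    return build_network(sample_out_degrees(n, gamma, g), g, gamma=gamma)


@pytest.fixture
def small_net():
    """A fixed 40-node near-critical network."""
    return make_net(40, 1.9, seed=7)


@pytest.fixture
def chain_net():
    """0 -> 1 -> 2 chain with positive weights (node 0 is the hub)."""
    return ThresholdNetwork(3, src=[0, 1], tgt=[1, 2], weight=[0.8, 0.9])
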