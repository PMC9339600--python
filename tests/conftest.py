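import networkx as nx
import numpy as np
import pytest

from isovrnet import SimConfig, SilenceIntervals, couple_layers, make_fixture


@pytest.fixture
def rho():
    return SilenceIntervals(-0.4, -0.2, 0.2, 0.3)


@pytest.fixture
def small_config():
    """Fast two-layer configuration for trajectory tests."""
    return SimConfig(n=60, m=3, seed=7, horizon=25, initial_carriers=4,
                     offline_prob=0.5, immune_start=8)


@pytest.fixture
def toy12():
    return make_fixture("toy12", seed=11)


@pytest.fixture
def star_pair():
    g1, g2 = nx.star_graph(4), nx.star_graph(4)
    return g1, g2


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    g.add_nodes_from(range(n))
    return g
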