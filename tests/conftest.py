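import networkx as nx
import numpy as np
import pytest

import vaxgame as vg
from vaxgame.decision import _Workspace


def make_network(edges):
    """Build a ContactNetwork from (u, v, w) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return vg.ContactNetwork(g)


@pytest.fixture
def triangle():
    return make_network([(0, 1, 5.0), (1, 2, 3.0), (0, 2, 1.0)])


@pytest.fixture
def star():
    """Hub 0 with four leaves, all weights 2."""
    return make_network([(0, i, 2.0) for i in range(1, 5)])


@pytest.fixture(scope="session")
def highschool():
    """One realization of the high-school preset, shared across tests."""
    return vg.generate_synthetic(vg.HIGHSCHOOL, seed=0)


@pytest.fixture(scope="session")
def highschool_ws(highschool):
    return _Workspace(highschool)


@pytest.fixture(scope="session")
def small_net():
    """Small synthetic network for fast sweep tests."""
    spec = vg.GeneratorSpec(n_nodes=60, mean_degree=6.0, mean_weight=115.0)
    return vg.generate_synthetic(spec, seed=3)


def rng_for(*key):
    return np.random.default_rng(np.random.SeedSequence(2024, spawn_key=key))
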