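"""Shared fixtures: tiny hand-built networks and similarity stores."""

import numpy as np
import pytest

from gasoline.core_model import Network, SimilarityStore


def make_network(species, edges, extra_nodes=()):
    """Build a Network from (u, v) or (u, v, w) tuples."""
    net = Network(species)
    for e in edges:
        if len(e) == 2:
            net.add_edge(e[0], e[1], 1.0)
        else:
            net.add_edge(e[0], e[1], e[2])
    for x in extra_nodes:
        net.add_node(x)
    return net


def make_sim(pairs, mode="bitscore"):
    """Build a SimilarityStore from (net_a, a, net_b, b, score) tuples."""
    store = SimilarityStore(mode=mode)
    for na, a, nb, b, s in pairs:
        store.add(na, a, nb, b, s)
    return store


def clique_network(species, nodes):
    net = Network(species)
    nodes = list(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            net.add_edge(u, v, 1.0)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles():
    """Two species whose aligned subgraphs are identical triangles."""
    net_a = clique_network("A", ["a1", "a2", "a3"])
    net_b = clique_network("B", ["b1", "b2", "b3"])
    sim = make_sim([
        ("A", "a1", "B", "b1", 100.0),
        ("A", "a2", "B", "b2", 100.0),
        ("A", "a3", "B", "b3", 100.0),
    ])
    return net_a, net_b, sim
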