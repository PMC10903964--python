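import networkx as nx
import numpy as np
import pytest

from vesselprune import VascularNetwork


def make_network(edges, positions=None, diameters=None, lengths=None):
    """Small-network builder: edges as (a, b) pairs, ids in order."""
    net = VascularNetwork()
    nodes = sorted({n for e in edges for n in e})
    for n in nodes:
        x, y = (positions or {}).get(n, (float(n), 0.0))
        net.add_node(n, x, y)
    for vid, (a, b) in enumerate(edges):
        d = (diameters or {}).get(vid, 10.0)
        L = (lengths or {}).get(vid, 50.0)
        net.add_vessel(vid, a, b, d, L)
    return net


def random_network(rng, n_nodes=8, extra_edges=2):
    """Random connected network: a random tree plus loop chords."""
    g = nx.random_labeled_tree(n_nodes, seed=int(rng.integers(2**31)))
    edges = list(g.edges())
    candidates = [(a, b) for a in range(n_nodes) for b in range(a + 1, n_nodes)
                  if not g.has_edge(a, b)]
    if candidates and extra_edges:
        take = rng.choice(len(candidates),
                          size=min(extra_edges, len(candidates)), replace=False)
        edges += [candidates[i] for i in np.atleast_1d(take)]
    pos = {n: (float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
           for n in range(n_nodes)}
    diam = {i: float(rng.uniform(5, 40)) for i in range(len(edges))}
    return make_network(edges, positions=pos, diameters=diam)


@pytest.fixture
def y_graph():
    """Y-shaped tree: one centre node, three leaves."""
    return make_network([(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def four_cycle():
    return make_network([(0, 1), (1, 2), (2, 3), (3, 0)])
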