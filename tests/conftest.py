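import networkx as nx
import numpy as np
import pytest

from steinermark import generate_scenario


def unit_graph(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=1.0)
    return g


@pytest.fixture
def star_net():
    """Center 'c' joined to leaves a, b, d."""
    return unit_graph([("c", "a"), ("c", "b"), ("c", "d")])


@pytest.fixture
def path_net():
    """Path a-b-c-d."""
    return unit_graph([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def cycle_net():
    """4-cycle a-b-c-d-a."""
    return unit_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 12, p: float = 0.35) -> nx.Graph:
    """Seeded Erdos-Renyi graph resampled until connected, unit weights, string labels."""
    while True:
        n = int(rng.integers(4, max_nodes + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-size planted scenario shared by discovery/evaluation tests."""
    return generate_scenario(
        n_nodes=300,
        edges_per_node=3,
        n_de=30,
        n_connectors=6,
        n_samples=60,
        effect_size=2.0,
        noise_sd=1.0,
        seed=11,
    )
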