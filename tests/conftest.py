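import networkx as nx
import numpy as np
import pytest

from netprio import default_scenario


@pytest.fixture
def two_k4_bridge() -> nx.Graph:
    """Two K4 cliques joined by a single bridge edge A0-B0."""
    g = nx.Graph()
    for p in ("A", "B"):
        ns = [f"{p}{i}" for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(ns[i], ns[j])
    g.add_edge("A0", "B0")
    return g


@pytest.fixture(scope="session")
def scenario():
    """The standard planted benchmark at its default conditions."""
    return default_scenario(1)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced planted benchmark for cheap structural tests."""
    return default_scenario(7, n_nodes=300, n_seeds=40, n_module=12)


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Erdos-Renyi conditioned on connectivity (resample until connected)."""
    while True:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(i, j)
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
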