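"""MCODE weighting/complexes and spectral modularity partitioning."""

import networkx as nx
import numpy as np
import pytest

from netprio import (
    core_numbers,
    mcode_clusters,
    mcode_weights,
    modularity,
    spectral_partition,
)

from conftest import random_connected_graph


# --- k-core ---------------------------------------------------------------

def test_core_numbers_triangle_and_path():
    assert set(core_numbers(nx.complete_graph(3)).values()) == {2}
    assert set(core_numbers(nx.path_graph(4)).values()) == {1}


def test_core_numbers_k5_with_pendant():
    g = nx.complete_graph(5)
    g.add_edge(0, "PEND")
    cores = core_numbers(g)
    assert cores["PEND"] == 1
    assert all(cores[i] == 4 for i in range(5))


# --- vertex weights -------------------------------------------------------

def test_mcode_weight_triangle_member():
    assert mcode_weights(nx.complete_graph(3))[0] == pytest.approx(2.0)


def test_mcode_weight_k4_member():
    assert mcode_weights(nx.complete_graph(4))[0] == pytest.approx(3.0)


def test_mcode_weight_single_edge_endpoint():
    g = nx.Graph([("A", "B")])
    w = mcode_weights(g)
    assert w["A"] == pytest.approx(1.0) and w["B"] == pytest.approx(1.0)


def test_mcode_weight_isolated_node_is_zero():
    g = nx.Graph()
    g.add_node("LONER")
    assert mcode_weights(g)["LONER"] == 0.0


# --- complexes ------------------------------------------------------------

def test_single_k5_is_one_cluster_scored_five():
    g = nx.relabel_nodes(nx.complete_graph(5), {i: f"N{i}" for i in range(5)})
    clusters = mcode_clusters(g)
    assert len(clusters) == 1
    assert clusters[0].members == frozenset(g.nodes)
    assert clusters[0].score == pytest.approx(5.0)


def test_k6_with_pendant_chain_yields_only_the_k6():
    g = nx.relabel_nodes(nx.complete_graph(6), {i: f"K{i}" for i in range(6)})
    g.add_edges_from([("K0", "PA"), ("PA", "PB"), ("PB", "PC")])
    clusters = mcode_clusters(g)
    assert len(clusters) == 1
    assert clusters[0].members == frozenset(f"K{i}" for i in range(6))


def test_two_bridged_k4s_give_two_clusters_of_four(two_k4_bridge):
    clusters = mcode_clusters(two_k4_bridge)
    assert [len(c) for c in clusters] == [4, 4]
    assert {frozenset(c.members) for c in clusters} == {
        frozenset({"A0", "A1", "A2", "A3"}),
        frozenset({"B0", "B1", "B2", "B3"}),
    }


def test_mcode_clusters_are_disjoint_and_connected(scenario):
    from netprio import build_interactome

    inter = build_interactome(scenario.network, scenario.seeds)
    clusters = mcode_clusters(inter.graph)
    seen = set()
    for c in clusters:
        assert not (c.members & seen)
        seen |= c.members
        assert nx.is_connected(inter.graph.subgraph(c.members))
        # haircut guarantee: every member keeps >=2 within-cluster edges
        sub = inter.graph.subgraph(c.members)
        assert all(sub.degree(v) >= 2 for v in c.members)


def test_mcode_stable_under_relabelling(two_k4_bridge):
    mapping = {v: f"X{v}" for v in two_k4_bridge.nodes}
    relabelled = nx.relabel_nodes(two_k4_bridge, mapping)
    orig = {frozenset(mapping[m] for m in c.members)
            for c in mcode_clusters(two_k4_bridge)}
    new = {frozenset(c.members) for c in mcode_clusters(relabelled)}
    assert orig == new


def test_empty_graph_yields_no_clusters():
    assert mcode_clusters(nx.Graph()) == []


# --- spectral partitioning ------------------------------------------------

def _set_partitions(items):
    """All partitions of a list into non-empty blocks (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _partition_q(g: nx.Graph, parts) -> float:
    """Modularity computed from scratch (independent of the implementation)."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for block in parts:
        block = set(block)
        e_c = sum(1 for u, v in g.edges if u in block and v in block)
        d_c = sum(g.degree(v) for v in block)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def brute_force_best_partition_q(g: nx.Graph) -> float:
    """Exhaustive maximum modularity over ALL partitions of the node set."""
    return max(_partition_q(g, parts) for parts in _set_partitions(list(g.nodes)))


def test_two_bridged_k4s_recovered_with_known_q(two_k4_bridge):
    clusters, q = spectral_partition(two_k4_bridge)
    assert {frozenset(c.members) for c in clusters} == {
        frozenset({"A0", "A1", "A2", "A3"}),
        frozenset({"B0", "B1", "B2", "B3"}),
    }
    # Q = 2 * (6/13 - (13/26)^2)
    assert q == pytest.approx(2 * (6 / 13 - 0.25), abs=1e-9)
    assert q == pytest.approx(0.4231, abs=5e-5)


def test_complete_graph_is_not_split():
    clusters, q = spectral_partition(nx.complete_graph(6))
    assert len(clusters) == 1
    assert q == pytest.approx(0.0, abs=1e-12)


def test_spectral_q_bounded_by_partition_oracle():
    """On small graphs: algorithm's Q never beats the exhaustive maximum over
    all partitions, and finds positive Q whenever strong structure exists."""
    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(6, 10))
        g = random_connected_graph(n, 0.35, rng)
        _, q = spectral_partition(g)
        best = brute_force_best_partition_q(g)
        assert q <= best + 1e-9
        if best > 0.1:
            assert q > 0.0


def test_spectral_matches_igraph_on_bridged_cliques(two_k4_bridge):
    """Independent cross-check against igraph's leading-eigenvector method."""
    igraph = pytest.importorskip("igraph")
    nodes = sorted(two_k4_bridge.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    ig = igraph.Graph(
        n=len(nodes), edges=[(idx[u], idx[v]) for u, v in two_k4_bridge.edges]
    )
    ref = ig.community_leading_eigenvector()
    ref_comms = {frozenset(nodes[i] for i in c) for c in ref}
    ours = {frozenset(c.members) for c in spectral_partition(two_k4_bridge)[0]}
    assert ours == ref_comms


def test_modularity_of_trivial_partition_is_zero(two_k4_bridge):
    assert modularity(two_k4_bridge, [list(two_k4_bridge.nodes)]) == pytest.approx(0.0)


def test_spectral_partitions_cover_all_nodes(scenario):
    from netprio import build_interactome, extract_men, rank_nodes

    inter = build_interactome(scenario.network, scenario.seeds)
    men = extract_men(inter.graph, rank_nodes(inter.graph))
    clusters, q = spectral_partition(men.subgraph)
    covered = set().union(*(c.members for c in clusters))
    assert covered == set(men.subgraph.nodes)
    assert -0.5 <= q < 1.0
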