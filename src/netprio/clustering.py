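"""Functional cluster detection: MCODE-style complexes and spectral partitioning.

MCODE weights each vertex by ``k * density`` of the highest k-core of its
closed neighbourhood, then grows complexes from the highest-weight unvisited
vertex. Expansion here is single-level: the complex is the seed vertex plus
those direct neighbours whose weight exceeds ``(1 - vwp)`` times the seed's
weight. The optional *haircut* removes members with fewer than two
within-complex edges (single pass); trimmed vertices return to the unvisited
pool so a dense region attached by a bridge can still found its own complex.
The seed vertex is always marked visited, which guarantees termination, and
surviving members are marked visited, which keeps complexes disjoint.

Spectral partitioning is recursive leading-eigenvector bisection of the
modularity matrix ``B = A - k k^T / 2m`` (generalised on subgraphs); a split
is accepted only if it increases the modularity Q.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Cluster",
    "core_numbers",
    "mcode_weights",
    "mcode_clusters",
    "spectral_partition",
    "modularity",
]


@dataclass
class Cluster:
    """A connected node set found by one of the clustering methods."""

    method: str  # "mcode" | "spectral"
    members: frozenset[str]
    score: float
    seed_node: str | None = None  # MCODE only
    cluster_id: str = ""

    def __len__(self) -> int:
        return len(self.members)


def core_numbers(graph: nx.Graph) -> dict[str, int]:
    """Standard k-core decomposition (largest k whose maximal subgraph of
    minimum degree k contains the node)."""
    if graph.number_of_nodes() == 0:
        return {}
    return nx.core_number(graph)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return g.number_of_edges() / (n * (n - 1) / 2)


def mcode_weights(graph: nx.Graph) -> dict[str, float]:
    """Vertex weight = k * density of the highest k-core of N[v].

    Isolated vertices weigh 0. ``k`` is the core level of the main core of
    the closed neighbourhood and density is edges over possible pairs within
    that core.
    """
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbrs = set(graph.neighbors(v))
        if not nbrs:
            weights[v] = 0.0
            continue
        closed = graph.subgraph(nbrs | {v})
        cores = nx.core_number(closed)
        k = max(cores.values())
        main_core = closed.subgraph([u for u, c in cores.items() if c >= k])
        weights[v] = k * _density(main_core)
    return weights


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    """Single-pass removal of members with < 2 within-cluster edges."""
    sub = graph.subgraph(members)
    return {v for v in members if sub.degree(v) >= 2}


def mcode_clusters(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
    min_size: int = 3,
) -> list[Cluster]:
    """Disjoint MCODE complexes, scored density * size, best first.

    Complexes are seeded from the highest-weight unvisited vertex (ties by
    ascending symbol) and contain the seed plus its unvisited neighbours
    with weight strictly above ``(1 - vwp) * seed weight``. With ``fluff``,
    unvisited neighbours of members whose closed-neighbourhood density
    exceeds ``fluff_density`` are appended in a single pass (before
    haircut). Complexes smaller than ``min_size`` after post-processing are
    dropped.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must be in [0, 1)")
    weights = mcode_weights(graph)
    unvisited = set(graph.nodes)
    clusters: list[Cluster] = []
    while unvisited:
        seed = min(unvisited, key=lambda v: (-weights[v], v))
        unvisited.discard(seed)
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        for nb in graph.neighbors(seed):
            if nb in unvisited and weights[nb] > threshold:
                members.add(nb)
        if fluff:
            for m in sorted(members):
                for nb in graph.neighbors(m):
                    if nb in unvisited and nb not in members:
                        closed = graph.subgraph(set(graph.neighbors(nb)) | {nb})
                        if _density(closed) > fluff_density:
                            members.add(nb)
        if haircut:
            kept = _haircut(graph, members)
        else:
            kept = set(members)
        unvisited -= kept
        # seed stays visited even if haircut dropped it; other trimmed
        # vertices return to the pool
        if len(kept) >= min_size:
            sub = graph.subgraph(kept)
            score = _density(sub) * len(kept)
            clusters.append(
                Cluster(method="mcode", members=frozenset(kept), score=score, seed_node=seed)
            )
    clusters.sort(key=lambda c: (-c.score, -len(c.members), sorted(c.members)[0]))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"M{i:03d}"
    return clusters


# ---------------------------------------------------------------------------
# spectral modularity partitioning
# ---------------------------------------------------------------------------

def modularity(graph: nx.Graph, communities: Iterable[Iterable[str]]) -> float:
    """Q = sum_c [ m_c/m - (D_c / 2m)^2 ] over the given partition."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        comm = set(comm)
        m_c = graph.subgraph(comm).number_of_edges()
        d_c = sum(graph.degree(v) for v in comm)
        q += m_c / m - (d_c / (2 * m)) ** 2
    return q


def _leading_split(b_sub: np.ndarray) -> np.ndarray | None:
    """Sign vector of the leading eigenvector, or None if no positive split."""
    vals, vecs = np.linalg.eigh((b_sub + b_sub.T) / 2.0)
    lead = vecs[:, -1]
    if vals[-1] <= 1e-12:
        return None
    # deterministic sign: first nonzero entry positive
    nz = np.nonzero(np.abs(lead) > 1e-12)[0]
    if nz.size and lead[nz[0]] < 0:
        lead = -lead
    s = np.where(lead >= 0.0, 1.0, -1.0)
    if np.all(s == s[0]):
        return None
    return s


def spectral_partition(graph: nx.Graph) -> tuple[list[Cluster], float]:
    """Recursive leading-eigenvector bisection; returns communities and Q.

    Each candidate bisection uses the generalised modularity matrix
    ``B^(g)_ij = B_ij - delta_ij * sum_k B_ik`` restricted to the group and
    is accepted only when it increases Q. Disconnected graphs are handled
    per connected component.
    """
    nodes = sorted(graph.nodes)
    m = graph.number_of_edges()
    if not nodes:
        return [], 0.0
    if m == 0:
        comms = [[v] for v in nodes]
        clusters = _as_spectral_clusters(graph, comms)
        return clusters, 0.0

    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.edges:
        a[pos[u], pos[v]] = 1.0
        a[pos[v], pos[u]] = 1.0
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / (2.0 * m)

    final: list[list[str]] = []

    def divide(idx: np.ndarray) -> None:
        if idx.size <= 1:
            final.append([nodes[i] for i in idx])
            return
        b_sub = b[np.ix_(idx, idx)]
        b_gen = b_sub - np.diag(b_sub.sum(axis=1))
        s = _leading_split(b_gen)
        if s is None:
            final.append([nodes[i] for i in idx])
            return
        delta_q = float(s @ b_gen @ s) / (4.0 * m)
        if delta_q <= 1e-12:
            final.append([nodes[i] for i in idx])
            return
        divide(idx[s > 0])
        divide(idx[s < 0])

    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        divide(np.array(sorted(pos[v] for v in comp), dtype=np.int64))

    q = modularity(graph, final)
    return _as_spectral_clusters(graph, final), q


def _as_spectral_clusters(graph: nx.Graph, comms: list[list[str]]) -> list[Cluster]:
    m = graph.number_of_edges()
    out: list[Cluster] = []
    for comm in comms:
        cset = set(comm)
        if m > 0:
            m_c = graph.subgraph(cset).number_of_edges()
            d_c = sum(graph.degree(v) for v in cset)
            contrib = m_c / m - (d_c / (2 * m)) ** 2
        else:
            contrib = 0.0
        out.append(Cluster(method="spectral", members=frozenset(cset), score=contrib))
    out.sort(key=lambda c: (-len(c.members), -c.score, sorted(c.members)[0]))
    for i, c in enumerate(out, start=1):
        c.cluster_id = f"S{i:03d}"
    return out
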