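"""Node ranking by connectivity and bottleneck; minimal-essential-network extraction.

Each node is scored on two topological axes: *connectivity* (degree) and
*bottleneck* (unnormalised betweenness centrality — the fraction-weighted
count of shortest paths passing through the node). Nodes are ranked
descending on each metric (min-rank for ties) and the two ranks are summed
into a combined score. The minimal essential network (MEN) is the top
decile of nodes by that combined score: the ``ceil(fraction * N)`` nodes
with the smallest score, boundary ties broken by higher degree, then higher
betweenness, then ascending symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["NodeRanking", "MinimalEssentialNetwork", "betweenness", "rank_nodes", "extract_men"]


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Unnormalised betweenness over unordered source-target pairs.

    For node v: sum over pairs (s, t), s != v != t, of the fraction of
    shortest s-t paths passing through v. Computed exactly by Brandes
    accumulation; disconnected graphs are handled by the pair-counting
    definition (pairs in different components contribute nothing).
    """
    return nx.betweenness_centrality(graph, normalized=False)


@dataclass
class NodeRanking:
    """Per-node degree/betweenness with per-metric min-ranks and combined score."""

    table: pd.DataFrame  # index: symbol; columns: degree, betweenness,
    #                      rank_degree, rank_betweenness, combined_rank_score

    def order(self) -> list[str]:
        """Symbols best-first: combined score, then the MEN tie-break."""
        t = self.table
        idx = sorted(
            t.index,
            key=lambda s: (
                t.at[s, "combined_rank_score"],
                -t.at[s, "degree"],
                -t.at[s, "betweenness"],
                s,
            ),
        )
        return idx


def rank_nodes(graph: nx.Graph) -> NodeRanking:
    """Degree and betweenness with descending min-ranks and their sum."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty graph")
    nodes = sorted(graph.nodes)
    deg = np.array([graph.degree(n) for n in nodes], dtype=float)
    btw_map = betweenness(graph)
    btw = np.array([btw_map[n] for n in nodes], dtype=float)
    rank_deg = rankdata(-deg, method="min").astype(int)
    rank_btw = rankdata(-btw, method="min").astype(int)
    table = pd.DataFrame(
        {
            "degree": deg.astype(int),
            "betweenness": btw,
            "rank_degree": rank_deg,
            "rank_betweenness": rank_btw,
            "combined_rank_score": rank_deg + rank_btw,
        },
        index=pd.Index(nodes, name="symbol"),
    )
    return NodeRanking(table)


@dataclass
class MinimalEssentialNetwork:
    """The retained top-ranked nodes and their induced subgraph."""

    nodes: list[str]  # ordered best-first
    subgraph: nx.Graph
    retention_fraction: float

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.subgraph

    def __len__(self) -> int:
        return len(self.nodes)


def extract_men(
    graph: nx.Graph,
    ranking: NodeRanking | None = None,
    retention_fraction: float = 0.10,
    combine: str = "rank_sum",
) -> MinimalEssentialNetwork:
    """Retain the top ``ceil(fraction * N)`` nodes by combined rank.

    ``combine="rank_sum"`` (default) keeps exactly ``ceil(fraction * N)``
    nodes with the smallest degree-rank + betweenness-rank sum, ties at the
    boundary broken by (higher degree, higher betweenness, ascending
    symbol). ``combine="union"`` instead keeps the union of the per-metric
    top deciles (sensitivity-analysis mode; size is then >= the decile).
    """
    if not 0.0 < retention_fraction <= 1.0:
        raise ValueError("retention_fraction must be in (0, 1]")
    if combine not in ("rank_sum", "union"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if ranking is None:
        ranking = rank_nodes(graph)
    t = ranking.table
    n = len(t)
    n_keep = math.ceil(retention_fraction * n)
    if combine == "rank_sum":
        retained = ranking.order()[:n_keep]
    else:
        # union mode: per-metric deciles, each with the ascending-symbol tie-break
        by_deg = sorted(t.index, key=lambda s: (t.at[s, "rank_degree"], s))[:n_keep]
        by_btw = sorted(t.index, key=lambda s: (t.at[s, "rank_betweenness"], s))[:n_keep]
        union = set(by_deg) | set(by_btw)
        retained = [s for s in ranking.order() if s in union]
    sub = nx.Graph(graph.subgraph(retained))
    return MinimalEssentialNetwork(
        nodes=retained, subgraph=sub, retention_fraction=retention_fraction
    )
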