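"""Seed-induced interactome construction.

The interactome is the subnetwork of a background protein-protein
interaction graph consisting of the seed (disease-associated) genes present
in the background plus their immediate interaction partners. By default
only edges incident to a seed are kept: a disease interactome built this
way over a hub-rich interaction database stays sparse (roughly one to two
edges per node), whereas the full induced subgraph would import every
edge among the partners of promiscuous hubs and drown the seed-centred
topology. The full induced subgraph (``include_neighbor_edges=True``) is
exposed for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .netio import EdgeList, normalise_symbol

log = logging.getLogger("netprio.interactome")

__all__ = ["Interactome", "build_interactome"]


@dataclass
class Interactome:
    """Simple undirected graph over gene symbols with per-node seed flags."""

    graph: nx.Graph
    seeds_found: list[str]
    seeds_missing: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_seeds_found(self) -> int:
        return len(self.seeds_found)

    @property
    def n_seeds_missing(self) -> int:
        return len(self.seeds_missing)

    def is_seed(self, node: str) -> bool:
        return bool(self.graph.nodes[node].get("is_seed", False))


def build_interactome(
    edges: EdgeList | Iterable[tuple[str, str]],
    seeds: Sequence[str],
    include_neighbor_edges: bool = False,
) -> Interactome:
    """Seeds present in the background plus their first neighbours.

    By default only edges incident to a seed are kept; with
    ``include_neighbor_edges`` the result is the full induced subgraph on
    seeds and neighbours. Seeds absent from the background (or isolated there) are reported
    in ``seeds_missing``, not fatal — but finding no seed at all is an error.
    """
    edge_pairs = edges.edges if isinstance(edges, EdgeList) else list(edges)
    source = nx.Graph()
    source.add_edges_from(edge_pairs)

    norm_seeds: list[str] = []
    seen: set[str] = set()
    for s in seeds:
        sym = normalise_symbol(s)
        if sym not in seen:
            seen.add(sym)
            norm_seeds.append(sym)
    if not norm_seeds:
        raise ValueError("no seeds supplied after normalisation")

    found = [s for s in norm_seeds if s in source]
    missing = [s for s in norm_seeds if s not in source]
    if not found:
        raise ValueError("none of the seed genes occur in the source network")
    if missing:
        log.info("%d of %d seeds absent from the source network", len(missing), len(norm_seeds))

    seed_set = set(found)
    nodes = set(found)
    for s in found:
        nodes.update(source.neighbors(s))

    g = nx.Graph()
    g.add_nodes_from(nodes)
    if include_neighbor_edges:
        g.add_edges_from(source.subgraph(nodes).edges())
    else:
        g.add_edges_from(
            (u, v) for u, v in source.edges(found) if u in nodes and v in nodes
        )
    for n in g.nodes:
        g.nodes[n]["is_seed"] = n in seed_set
    return Interactome(graph=g, seeds_found=found, seeds_missing=missing)
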