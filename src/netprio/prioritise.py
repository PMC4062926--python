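"""Integration of network topology, permutation significance and expression.

A gene is *prioritised* when it (a) sits in the minimal essential network,
(b) is a seed whose permutation connectivity p-value passes alpha, and
(c) carries direction-consistent differential-expression support in at
least one contrast. Prioritised genes are then annotated with the MCODE
complex that contains them, giving per-cluster reports of the candidate
disease machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .clustering import Cluster
from .expression import ConcordanceTable
from .permnull import PermutationResult
from .topology import MinimalEssentialNetwork

__all__ = ["PrioritisedGene", "men_perm_overlap", "prioritise", "assign_clusters"]


@dataclass
class PrioritisedGene:
    symbol: str
    in_men: bool
    perm_p: float
    contrasts_supported: list[tuple[str, str]] = field(default_factory=list)  # (contrast, direction)
    containing_cluster_id: str | None = None


def men_perm_overlap(
    men: MinimalEssentialNetwork,
    perm: PermutationResult,
    alpha: float = 0.05,
) -> set[str]:
    """MEN members that are seeds with permutation p <= alpha."""
    men_nodes = set(men.nodes)
    return {s for s, p in perm.per_seed_p.items() if p <= alpha and s in men_nodes}


def prioritise(
    candidates: set[str],
    concordances: Sequence[ConcordanceTable],
    perm: PermutationResult,
) -> list[PrioritisedGene]:
    """Join candidates to per-contrast up/down lists; drop unsupported genes.

    Output is sorted by ascending permutation p, ties by ascending symbol.
    """
    out: list[PrioritisedGene] = []
    for gene in sorted(candidates):
        supported: list[tuple[str, str]] = []
        for conc in concordances:
            if gene in conc.up:
                supported.append((conc.contrast, "up"))
            elif gene in conc.down:
                supported.append((conc.contrast, "down"))
        if not supported:
            continue
        out.append(
            PrioritisedGene(
                symbol=gene,
                in_men=True,
                perm_p=perm.per_seed_p.get(gene, 1.0),
                contrasts_supported=supported,
            )
        )
    out.sort(key=lambda g: (g.perm_p, g.symbol))
    return out


def assign_clusters(
    prioritised: Sequence[PrioritisedGene],
    clusters: Sequence[Cluster],
) -> tuple[list[PrioritisedGene], dict[str, list[str]]]:
    """Annotate each prioritised gene with its (disjoint) containing cluster.

    Returns the annotated genes plus a report mapping cluster id to the
    prioritised genes it contains (clusters with none are omitted).
    """
    membership: dict[str, str] = {}
    seen: set[str] = set()
    for c in clusters:
        overlap = c.members & seen
        if overlap:
            raise ValueError(f"clusters are not disjoint: {sorted(overlap)[:5]}")
        seen |= c.members
        for gene in c.members:
            membership[gene] = c.cluster_id
    report: dict[str, list[str]] = {}
    for g in prioritised:
        cid = membership.get(g.symbol)
        g.containing_cluster_id = cid
        if cid is not None:
            report.setdefault(cid, []).append(g.symbol)
    for cid in report:
        report[cid].sort()
    return list(prioritised), report
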