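"""Synthetic benchmark data with known planted structure.

Every downstream stage of the pipeline is testable without external
databases: this module generates

* a scale-free background network (preferential attachment grown from an
  initial clique, which pins the edge count in closed form),
* a seed-gene set containing a planted over-connected module,
* pathway gene sets including one designed to be enriched in the module,
* expression studies with group effects planted on the module genes,

and records the ground truth so recovery can be scored exactly.

All generators are deterministic given their ``rng_seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .netio import EdgeList, ExpressionStudy, GeneSetCollection

import pandas as pd

__all__ = [
    "SyntheticTruth",
    "generate_ppi_network",
    "plant_seed_module",
    "generate_pathway_sets",
    "generate_expression",
    "default_scenario",
    "Scenario",
]


def _symbol(i: int, width: int = 4) -> str:
    return f"G{i:0{width}d}"


@dataclass
class SyntheticTruth:
    """Ground truth of a planted scenario.

    ``module_genes`` are the over-connected, expression-perturbed genes;
    they are always a subset of ``seed_genes``. ``de_genes_per_contrast``
    maps a contrast label to the planted (up, down) gene sets.
    """

    module_genes: set[str] = field(default_factory=set)
    seed_genes: set[str] = field(default_factory=set)
    enriched_pathway_id: str | None = None
    de_genes_per_contrast: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)
    rng_seed: int = 0
    n_planted_edges: int = 0

    def validate(self, network_nodes: set[str]) -> None:
        if not self.module_genes <= self.seed_genes:
            raise ValueError("module genes must be a subset of seed genes")
        for label, (up, down) in self.de_genes_per_contrast.items():
            if up & down:
                raise ValueError(f"contrast {label}: up/down gene sets overlap")
        stray = (self.seed_genes | self.module_genes) - network_nodes
        if stray:
            raise ValueError(f"truth genes absent from network: {sorted(stray)[:5]}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "seed_genes": sorted(self.seed_genes),
            "enriched_pathway_id": self.enriched_pathway_id,
            "de_genes_per_contrast": {
                k: {"up": sorted(up), "down": sorted(down)}
                for k, (up, down) in self.de_genes_per_contrast.items()
            },
            "rng_seed": self.rng_seed,
            "n_planted_edges": self.n_planted_edges,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_ppi_network(n_nodes: int, m_attach: int, rng_seed: int) -> EdgeList:
    """Preferential-attachment background network over symbols G0001...

    Growth starts from a clique on ``m_attach + 1`` nodes; each subsequent
    node attaches to ``m_attach`` distinct existing nodes with probability
    proportional to degree. The resulting simple connected graph has exactly
    ``C(m+1, 2) + m * (n - m - 1)`` edges.
    """
    if m_attach < 1:
        raise ValueError("m_attach must be >= 1")
    if n_nodes < m_attach + 1:
        raise ValueError(f"n_nodes must be >= m_attach + 1 ({m_attach + 1})")
    rng = np.random.default_rng(rng_seed)
    width = max(4, len(str(n_nodes)))
    names = [_symbol(i + 1, width) for i in range(n_nodes)]

    edges: list[tuple[str, str]] = []
    # degree-weighted sampling via the repeated-endpoints urn
    urn: list[int] = []
    m = m_attach
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((names[i], names[j]) if names[i] < names[j] else (names[j], names[i]))
    for i in range(m + 1):
        urn.extend([i] * m)  # clique degree = m

    for new in range(m + 1, n_nodes):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(urn[rng.integers(len(urn))])
        for t in sorted(targets):
            a, b = names[new], names[t]
            edges.append((a, b) if a < b else (b, a))
            urn.append(t)
        urn.extend([new] * m)

    return EdgeList(edges, provenance=f"synthetic:pa(n={n_nodes},m={m_attach},seed={rng_seed})")


def plant_seed_module(
    network: EdgeList,
    n_seeds: int,
    n_module: int,
    p_within: float,
    rng_seed: int,
) -> tuple[EdgeList, SyntheticTruth]:
    """Sample seed genes and densify a module subset of them.

    ``n_seeds`` nodes are drawn uniformly as seeds; ``n_module`` of those
    form the module, and every absent within-module edge is added
    independently with probability ``p_within``. The truth records the seed
    and module sets and the number of edges actually added.
    """
    if not 0.0 <= p_within <= 1.0:
        raise ValueError("p_within must be in [0, 1]")
    if n_module > n_seeds:
        raise ValueError("n_module must be <= n_seeds")
    nodes = sorted(network.nodes)
    if n_seeds > len(nodes):
        raise ValueError("n_seeds exceeds network size")
    rng = np.random.default_rng(rng_seed)
    seeds = [nodes[i] for i in rng.choice(len(nodes), size=n_seeds, replace=False)]
    module = sorted(seeds[:n_module])

    existing = set(network.edges)
    added: list[tuple[str, str]] = []
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            pair = (module[i], module[j])
            if pair in existing:
                continue
            if rng.random() < p_within:
                added.append(pair)
    out = EdgeList(
        network.edges + added,
        provenance=network.provenance + f"+module(n={n_module},p={p_within})",
        n_dropped_selfloops=network.n_dropped_selfloops,
        n_dropped_duplicates=network.n_dropped_duplicates,
    )
    truth = SyntheticTruth(
        module_genes=set(module),
        seed_genes=set(seeds),
        rng_seed=rng_seed,
        n_planted_edges=len(added),
    )
    return out, truth


def generate_pathway_sets(
    genes: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    truth: SyntheticTruth,
    overlap_fraction: float,
    rng_seed: int,
) -> GeneSetCollection:
    """Random pathway sets plus one designed to be enriched in the module.

    The designated set contains ``ceil(overlap_fraction * |module|)`` module
    genes topped up with random non-module genes to a size drawn from
    ``size_range``; its id is recorded in ``truth.enriched_pathway_id``.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty gene universe")
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ValueError("size_range outside universe size")
    rng = np.random.default_rng(rng_seed)
    coll = GeneSetCollection()

    module = sorted(truth.module_genes)
    n_overlap = math.ceil(overlap_fraction * len(module))
    core = [module[i] for i in rng.choice(len(module), size=n_overlap, replace=False)] if n_overlap else []
    size = int(rng.integers(lo, hi + 1))
    size = max(size, len(core))
    pool = [g for g in genes if g not in set(core)]
    filler_idx = rng.choice(len(pool), size=size - len(core), replace=False)
    designated = set(core) | {pool[i] for i in filler_idx}
    coll.add("SET_PLANTED", "planted enriched pathway", designated)
    truth.enriched_pathway_id = "SET_PLANTED"

    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        coll.add(f"SET{k + 1:04d}", f"random set {k + 1}", {genes[i] for i in idx})
    return coll


def generate_expression(
    genes: Sequence[str],
    contrasts: Sequence[tuple[int, int]],
    effect_size: float,
    noise_sd: float,
    truth: SyntheticTruth,
    rng_seed: int,
    labels: Sequence[str] | None = None,
) -> list[ExpressionStudy]:
    """One Gaussian expression study per (n_case, n_control) comparison.

    Module genes are shifted by ``±effect_size`` in the case group. The sign
    is drawn once per (gene, contrast label) and recorded in
    ``truth.de_genes_per_contrast``, so comparisons sharing a label carry a
    consistent planted direction (the substrate of the concordance rule).
    ``labels`` defaults to a single shared contrast ``"C1"``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if labels is None:
        labels = ["C1"] * len(contrasts)
    if len(labels) != len(contrasts):
        raise ValueError("labels must align with contrasts")
    genes = list(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(rng_seed)

    module = sorted(truth.module_genes & set(genes))
    directions: dict[str, dict[str, int]] = {}
    for label in dict.fromkeys(labels):
        signs = rng.choice([1, -1], size=len(module))
        directions[label] = dict(zip(module, (int(s) for s in signs)))
        up = {g for g, s in directions[label].items() if s > 0}
        down = {g for g, s in directions[label].items() if s < 0}
        truth.de_genes_per_contrast[label] = (up, down)

    studies: list[ExpressionStudy] = []
    for k, ((n_case, n_control), label) in enumerate(zip(contrasts, labels)):
        if n_case < 1 or n_control < 1:
            raise ValueError("group sizes must be positive")
        n = n_case + n_control
        values = rng.normal(0.0, noise_sd, size=(len(genes), n)) if noise_sd > 0 else np.zeros((len(genes), n))
        for g in module:
            values[gene_pos[g], :n_case] += directions[label][g] * effect_size
        samples = [f"S{k + 1}_{j + 1:03d}" for j in range(n)]
        groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
        studies.append(
            ExpressionStudy(
                name=f"study{k + 1}_{label}",
                genes=genes,
                samples=samples,
                values=values,
                groups=groups,
            )
        )
    return studies


# ---------------------------------------------------------------------------
# the default benchmark scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully planted benchmark: network, seeds, pathways, expression, truth."""

    network: EdgeList
    seeds: list[str]
    pathways: GeneSetCollection
    studies: list[ExpressionStudy]
    truth: SyntheticTruth


def default_scenario(
    rng_seed: int,
    n_nodes: int = 2000,
    m_attach: int = 2,
    n_seeds: int = 150,
    n_module: int = 30,
    p_within: float = 0.3,
    n_pathway_sets: int = 50,
    pathway_size_range: tuple[int, int] = (20, 80),
    pathway_overlap: float = 1.0,
    n_studies: int = 3,
    group_sizes: tuple[int, int] = (20, 20),
    effect_size: float = 1.5,
    noise_sd: float = 1.0,
    contrast: str = "C1",
) -> Scenario:
    """The standard benchmark conditions used throughout the test suite.

    One deterministic child seed per generator is derived from ``rng_seed``
    so each stage is individually reproducible.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_net, s_mod, s_path, s_expr = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    base = generate_ppi_network(n_nodes, m_attach, s_net)
    network, truth = plant_seed_module(base, n_seeds, n_module, p_within, s_mod)
    truth.rng_seed = rng_seed
    pathways = generate_pathway_sets(
        sorted(network.nodes), n_pathway_sets, pathway_size_range, truth,
        pathway_overlap, s_path,
    )
    studies = generate_expression(
        sorted(network.nodes), [group_sizes] * n_studies, effect_size, noise_sd,
        truth, s_expr, labels=[contrast] * n_studies,
    )
    truth.validate(network.nodes)
    return Scenario(network, sorted(truth.seed_genes), pathways, studies, truth)
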