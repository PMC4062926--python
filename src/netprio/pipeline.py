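"""End-to-end orchestration: one config in, a result bundle and manifest out.

Stages run in workflow order: read inputs -> build the seed interactome ->
rank nodes and extract the minimal essential network -> degree-matched
permutation test on the background network -> MCODE complexes on the
interactome and spectral partitioning of the MEN -> pathway enrichment ->
per-study differential expression and per-contrast concordance ->
candidate overlap and prioritisation -> cluster assignment.

One global RNG seed is split deterministically per stage. Every output file
carries the package version; the manifest records per-stage counts, stage
timings and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import Cluster, mcode_clusters, spectral_partition
from .enrichment import enrich
from .expression import ConcordanceTable, DEStudyResult, concordance, de_anova, pca_outliers
from .interactome import Interactome, build_interactome
from .netio import (
    EdgeList,
    ExpressionStudy,
    GeneSetCollection,
    read_edge_list,
    read_expression,
    read_gene_sets_gmt,
    read_seed_list,
    write_edge_list,
)
from .permnull import PermutationResult, permutation_test
from .prioritise import PrioritisedGene, assign_clusters, men_perm_overlap, prioritise
from .topology import MinimalEssentialNetwork, NodeRanking, extract_men, rank_nodes

log = logging.getLogger("netprio.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline", "run_stages"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudySpec:
    matrix: Path
    annotation: Path
    contrast: str = "C1"
    comparison: tuple[str, str] = ("case", "control")


@dataclass
class PipelineConfig:
    edges: Path
    seeds: Path
    outdir: Path
    dialect: str = "simple"
    gene_sets: Path | None = None
    expression: list[StudySpec] = field(default_factory=list)
    rng_seed: int = 0
    include_neighbor_edges: bool = False
    retention_fraction: float = 0.10
    n_permutations: int = 10_000
    bin_min: int = 10
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    min_cluster_size: int = 3
    alpha_perm: float = 0.05
    alpha_de: float = 0.05
    min_support: int | None = None
    q_threshold: float = 0.05
    qc_outliers: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = raw.pop("params", {})
        expr = [
            StudySpec(
                matrix=Path(e["matrix"]),
                annotation=Path(e["annotation"]),
                contrast=str(e.get("contrast", "C1")),
                comparison=tuple(e.get("comparison", ("case", "control"))),
            )
            for e in raw.pop("expression", [])
        ]
        cfg = cls(
            edges=Path(raw["edges"]),
            seeds=Path(raw["seeds"]),
            outdir=Path(raw.get("outdir", "netprio_out")),
            dialect=raw.get("dialect", "simple"),
            gene_sets=Path(raw["gene_sets"]) if raw.get("gene_sets") else None,
            expression=expr,
            rng_seed=int(raw.get("rng_seed", 0)),
            **params,
        )
        return cfg

    def validate(self) -> None:
        for label, p in [("edges", self.edges), ("seeds", self.seeds)]:
            if not Path(p).is_file():
                raise FileNotFoundError(f"{label} file not found: {p}")
            if Path(p).stat().st_size == 0 or not _has_content(p):
                raise ValueError(f"{label} file is empty: {p}")
        if self.gene_sets is not None and not Path(self.gene_sets).is_file():
            raise FileNotFoundError(f"gene_sets file not found: {self.gene_sets}")
        for spec in self.expression:
            for p in (spec.matrix, spec.annotation):
                if not Path(p).is_file():
                    raise FileNotFoundError(f"expression file not found: {p}")
        if not 0.0 < self.retention_fraction <= 1.0:
            raise ValueError("retention_fraction must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must be in [0, 1)")
        for name in ("alpha_perm", "alpha_de", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _has_content(path: str | Path) -> bool:
    with Path(path).open() as fh:
        return any(line.strip() and not line.lstrip().startswith("#") for line in fh)


@dataclass
class PipelineResult:
    interactome: Interactome
    ranking: NodeRanking
    men: MinimalEssentialNetwork
    permutation: PermutationResult
    mcode: list[Cluster]
    spectral: list[Cluster]
    spectral_q: float
    men_enrichment: pd.DataFrame | None
    cluster_enrichment: dict[str, pd.DataFrame]
    de_results: list[DEStudyResult]
    concordances: list[ConcordanceTable]
    candidates: set[str]
    prioritised: list[PrioritisedGene]
    cluster_report: dict[str, list[str]]
    manifest: dict[str, Any]


def _stage_seeds(rng_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(rng_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_stages(
    edges: EdgeList,
    seeds: Sequence[str],
    gene_sets: GeneSetCollection | None,
    studies: Sequence[tuple[ExpressionStudy, str, tuple[str, str]]],
    config: PipelineConfig,
) -> PipelineResult:
    """Execute all stages on in-memory inputs (the core of ``run_pipeline``).

    ``studies`` holds (study, contrast label, (case, control)) triples.
    """
    timings: dict[str, float] = {}
    counts: dict[str, Any] = {}
    perm_seed, _ = _stage_seeds(config.rng_seed, 2)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %-14s %6.2fs", name, timings[name])
            return out
        return deco

    inter = stage("interactome")(
        lambda: build_interactome(edges, seeds, config.include_neighbor_edges)
    )
    counts["n_nodes"] = inter.n_nodes
    counts["n_edges"] = inter.n_edges
    counts["n_seeds_found"] = inter.n_seeds_found
    counts["n_seeds_missing"] = inter.n_seeds_missing

    ranking = stage("ranking")(lambda: rank_nodes(inter.graph))
    men = stage("men")(
        lambda: extract_men(inter.graph, ranking, config.retention_fraction)
    )
    counts["men_size"] = len(men)

    import networkx as nx

    background = nx.Graph()
    background.add_edges_from(edges.edges)
    perm = stage("permutation")(
        lambda: permutation_test(
            background,
            inter.seeds_found,
            n_permutations=config.n_permutations,
            bin_min=config.bin_min,
            rng_seed=perm_seed,
        )
    )
    counts["network_perm_p"] = perm.network_p
    counts["n_perm_significant_seeds"] = len(perm.significant_seeds(config.alpha_perm))

    mcode = stage("mcode")(
        lambda: mcode_clusters(
            inter.graph,
            vwp=config.vwp,
            haircut=config.haircut,
            fluff=config.fluff,
            min_size=config.min_cluster_size,
        )
    )
    counts["n_mcode_clusters"] = len(mcode)
    spectral, q = stage("spectral")(lambda: spectral_partition(men.subgraph))
    counts["n_spectral_communities"] = len(spectral)
    counts["spectral_q"] = round(q, 6)

    universe = set(inter.graph.nodes)
    men_enr: pd.DataFrame | None = None
    cluster_enr: dict[str, pd.DataFrame] = {}
    if gene_sets is not None:
        men_enr = stage("enrichment")(
            lambda: enrich(set(men.nodes), gene_sets, universe, config.q_threshold)
        )
        for c in mcode:
            cluster_enr[c.cluster_id] = enrich(
                set(c.members), gene_sets, universe, config.q_threshold
            )
        counts["n_men_enriched_sets"] = int(men_enr["significant"].sum()) if len(men_enr) else 0

    de_results: list[DEStudyResult] = []
    by_contrast: dict[str, list[DEStudyResult]] = {}
    for study, contrast, comparison in studies:
        def run_de(study=study, comparison=comparison):
            excl = pca_outliers(study) if config.qc_outliers else []
            return de_anova(study, comparison, alpha=config.alpha_de, exclude_samples=excl)
        res = stage(f"de:{study.name}")(run_de)
        de_results.append(res)
        by_contrast.setdefault(contrast, []).append(res)

    concordances: list[ConcordanceTable] = []
    for contrast in sorted(by_contrast):
        conc = stage(f"concordance:{contrast}")(
            lambda contrast=contrast: concordance(
                by_contrast[contrast], contrast=contrast, min_support=config.min_support
            )
        )
        concordances.append(conc)
        counts[f"concordant_up:{contrast}"] = len(conc.up)
        counts[f"concordant_down:{contrast}"] = len(conc.down)

    candidates = stage("overlap")(
        lambda: men_perm_overlap(men, perm, alpha=config.alpha_perm)
    )
    counts["n_candidates"] = len(candidates)
    prio = stage("prioritise")(lambda: prioritise(candidates, concordances, perm))
    prio, report = stage("clusters")(lambda: assign_clusters(prio, mcode))
    counts["n_prioritised"] = len(prio)
    counts["n_clusters_with_prioritised"] = len(report)

    manifest = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config_hash": config.digest(),
        "counts": counts,
        "timings_s": timings,
    }
    return PipelineResult(
        interactome=inter,
        ranking=ranking,
        men=men,
        permutation=perm,
        mcode=mcode,
        spectral=spectral,
        spectral_q=q,
        men_enrichment=men_enr,
        cluster_enrichment=cluster_enr,
        de_results=de_results,
        concordances=concordances,
        candidates=candidates,
        prioritised=prio,
        cluster_report=report,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Validate the config, run all stages, and write the result bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    edges = read_edge_list(config.edges, dialect=config.dialect)
    seeds = read_seed_list(config.seeds)
    gene_sets = read_gene_sets_gmt(config.gene_sets) if config.gene_sets else None
    studies = [
        (read_expression(s.matrix, s.annotation), s.contrast, s.comparison)
        for s in config.expression
    ]
    try:
        result = run_stages(edges, seeds, gene_sets, studies, config)
    except StageError as exc:
        failed_marker.write_text(f"{exc.stage}: {exc.cause}\n")
        raise
    _write_bundle(result, config, outdir)
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    head = f"# netprio {__version__} rng_seed={config.rng_seed}\n"

    nodes = sorted(result.interactome.graph.nodes)
    node_table = pd.DataFrame(
        {
            "symbol": nodes,
            "is_seed": [result.interactome.is_seed(n) for n in nodes],
            "degree": [result.interactome.graph.degree(n) for n in nodes],
            "in_men": [n in result.men for n in nodes],
        }
    )
    _tsv(node_table, outdir / "nodes.tsv", head)
    write_edge_list(sorted(result.interactome.graph.edges()), outdir / "interactome_edges.tsv",
                    rng_seed=config.rng_seed)

    rank = result.ranking.table.reset_index()
    rank["retained"] = rank["symbol"].isin(set(result.men.nodes))
    _tsv(rank, outdir / "ranking.tsv", head)
    write_edge_list(sorted(result.men.subgraph.edges()), outdir / "men_edges.tsv",
                    rng_seed=config.rng_seed)

    perm = result.permutation
    perm_table = pd.DataFrame(
        {
            "symbol": sorted(perm.per_seed_p),
            "stat": [perm.per_seed_stat[s] for s in sorted(perm.per_seed_p)],
            "p": [perm.per_seed_p[s] for s in sorted(perm.per_seed_p)],
        }
    )
    _tsv(perm_table, outdir / "permutation_seeds.tsv", head)
    (outdir / "permutation_summary.json").write_text(json.dumps({
        "observed_network_stat": perm.observed_network_stat,
        "network_p": perm.network_p,
        "n_permutations": perm.n_permutations,
        "bin_scheme": perm.bin_scheme,
    }, indent=1))

    rows = [
        {"cluster_id": c.cluster_id, "method": c.method, "score": c.score,
         "size": len(c), "members": ",".join(sorted(c.members))}
        for c in [*result.mcode, *result.spectral]
    ]
    _tsv(pd.DataFrame(rows), outdir / "clusters.tsv", head)

    if result.men_enrichment is not None:
        shown = result.men_enrichment[result.men_enrichment["k"] >= 1]
        _tsv(shown, outdir / "men_enrichment.tsv", head)

    for res in result.de_results:
        _tsv(res.table.reset_index(), outdir / f"de_{res.study}.tsv", head)
    for conc in result.concordances:
        _tsv(conc.table.reset_index(), outdir / f"concordance_{conc.contrast}.tsv", head)
        (outdir / f"up_{conc.contrast}.txt").write_text(head + "\n".join(conc.up) + "\n")
        (outdir / f"down_{conc.contrast}.txt").write_text(head + "\n".join(conc.down) + "\n")

    prio_rows = [
        {"symbol": g.symbol, "perm_p": g.perm_p, "contrast": c, "direction": d,
         "cluster_id": g.containing_cluster_id or ""}
        for g in result.prioritised
        for c, d in g.contrasts_supported
    ]
    _tsv(pd.DataFrame(prio_rows), outdir / "prioritised.tsv", head)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def _tsv(df: pd.DataFrame, path: Path, head: str) -> None:
    with path.open("w") as fh:
        fh.write(head)
        df.to_csv(fh, sep="\t", index=False)
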