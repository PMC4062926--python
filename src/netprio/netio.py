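"""Readers and writers for the external formats the pipeline touches.

Formats supported:

* simple edge list — two whitespace/tab-separated gene-symbol columns;
* a reduced BioGRID-tab dialect — tab-separated with a header row naming two
  official-symbol columns;
* GMT gene-set files (set-id TAB description TAB member...);
* expression matrices (genes x samples TSV) with a sample-annotation TSV.

All symbols are normalised (whitespace-trimmed, uppercased). Readers are
strict: a malformed row raises :class:`FormatError` naming the line number
rather than silently truncating. Writers prepend a ``#``-comment provenance
line with the package version (and RNG seed where one applies); readers skip
``#`` comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger("netprio.netio")

__all__ = [
    "FormatError",
    "EdgeList",
    "GeneSetCollection",
    "ExpressionStudy",
    "normalise_symbol",
    "read_edge_list",
    "write_edge_list",
    "read_seed_list",
    "write_seed_list",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_expression",
    "write_expression",
]


class FormatError(ValueError):
    """A file violated its declared dialect; the message names the line."""


def _provenance(rng_seed: int | None = None) -> str:
    tail = f" rng_seed={rng_seed}" if rng_seed is not None else ""
    return f"# netprio {__version__}{tail}\n"


def normalise_symbol(raw: str) -> str:
    """Trim whitespace and uppercase. Empty results are rejected."""
    sym = raw.strip().upper()
    if not sym:
        raise FormatError("empty gene symbol after normalisation")
    return sym


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Deduplicated undirected edges over normalised gene symbols.

    ``edges`` holds one ``(a, b)`` tuple per unordered pair with ``a < b``.
    """

    edges: list[tuple[str, str]]
    provenance: str = ""
    n_dropped_selfloops: int = 0
    n_dropped_duplicates: int = 0

    @property
    def nodes(self) -> set[str]:
        return {s for pair in self.edges for s in pair}

    def __len__(self) -> int:
        return len(self.edges)


def _dedupe_pairs(pairs: Iterable[tuple[str, str]]) -> tuple[list[tuple[str, str]], int, int]:
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    n_self = n_dup = 0
    for a, b in pairs:
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(key)
    return edges, n_self, n_dup


def read_edge_list(
    path: str | Path,
    dialect: str = "simple",
    symbol_columns: tuple[str, str] | None = None,
    filter_column: str | None = None,
    filter_values: set[str] | None = None,
) -> EdgeList:
    """Read an undirected edge list.

    ``dialect="simple"``: two whitespace-separated symbol columns per row.
    ``dialect="biogrid_tab"``: tab-separated with a header row; the two
    columns whose names contain "official symbol" (case-insensitive) are
    used, or the explicit ``symbol_columns``. ``filter_column`` /
    ``filter_values`` optionally restrict rows (e.g. to physical
    interactions); by default all rows are kept.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        if dialect == "simple":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                    )
                try:
                    pairs.append((normalise_symbol(fields[0]), normalise_symbol(fields[1])))
                except FormatError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
        elif dialect == "biogrid_tab":
            # the header is the first non-blank line; BioGRID prefixes it
            # with '#' ("#BioGRID Interaction ID\t...")
            header = None
            lineno = 0
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                header = line.rstrip("\n").lstrip("#").split("\t")
                break
            if header is None:
                log.warning("%s: empty edge-list file", path)
                return EdgeList([], provenance=str(path))
            if symbol_columns is None:
                cand = [c for c in header if "official symbol" in c.lower()]
                if len(cand) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: header has no two 'Official Symbol' columns"
                    )
                symbol_columns = (cand[0], cand[1])
            try:
                ia, ib = (header.index(c) for c in symbol_columns)
            except ValueError as exc:
                raise FormatError(f"{path}: {exc}") from None
            ifilt = header.index(filter_column) if filter_column else None
            for lineno, line in enumerate(fh, start=lineno + 1):
                if line.lstrip().startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) <= max(ia, ib):
                    raise FormatError(f"{path}:{lineno}: row has too few columns")
                if ifilt is not None and filter_values is not None:
                    if fields[ifilt] not in filter_values:
                        continue
                try:
                    pairs.append((normalise_symbol(fields[ia]), normalise_symbol(fields[ib])))
                except FormatError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
        else:
            raise ValueError(f"unknown edge-list dialect: {dialect!r}")

    edges, n_self, n_dup = _dedupe_pairs(pairs)
    if not edges and not pairs:
        log.warning("%s: empty edge list", path)
    return EdgeList(
        edges,
        provenance=str(path),
        n_dropped_selfloops=n_self,
        n_dropped_duplicates=n_dup,
    )


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path,
                    rng_seed: int | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(rng_seed))
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_seed_list(path: str | Path) -> list[str]:
    """One symbol per line; comments and blanks skipped; order-preserving dedupe."""
    out: list[str] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                sym = normalise_symbol(line)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    return out


def write_seed_list(seeds: Iterable[str], path: str | Path,
                    rng_seed: int | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_provenance(rng_seed))
        for s in seeds:
            fh.write(f"{s}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Map set-id -> (description, member set); ids unique, members normalised."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def add(self, set_id: str, description: str, members: Iterable[str]) -> None:
        if set_id in self.sets:
            raise FormatError(f"duplicate gene-set id {set_id!r}")
        self.sets[set_id] = (description, frozenset(normalise_symbol(m) for m in members))


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, desc, *members = fields
            try:
                coll.add(set_id.strip(), desc, [m for m in members if m.strip()])
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return coll


def write_gene_sets_gmt(coll: GeneSetCollection, path: str | Path,
                        rng_seed: int | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_provenance(rng_seed))
        for set_id, (desc, members) in coll.sets.items():
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """A genes x samples value matrix with per-sample group labels.

    ``covariates`` (optional) is a samples x covariates categorical frame
    aligned to ``samples``.
    """

    name: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    groups: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing from annotation: {missing[:5]}")
        self.groups = self.groups.loc[self.samples]
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.samples]

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples carrying ``label``."""
        mask = (self.groups.values == label)
        return np.nonzero(mask)[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def read_expression(
    matrix_path: str | Path,
    annotation_path: str | Path,
    name: str | None = None,
    collapse: str = "max_mean",
) -> ExpressionStudy:
    """Read a genes x samples TSV plus a sample-annotation TSV.

    The annotation needs columns ``sample`` and ``group``; any further
    columns are treated as categorical covariates. Duplicate gene rows are
    collapsed: ``max_mean`` keeps the row with the highest mean value,
    ``mean_of_rows`` averages them.
    """
    if collapse not in ("max_mean", "mean_of_rows"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    matrix_path = Path(matrix_path)
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    mat.index = [normalise_symbol(str(g)) for g in mat.index]
    annot = pd.read_csv(annotation_path, sep="\t", comment="#", dtype=str)
    for col in ("sample", "group"):
        if col not in annot.columns:
            raise FormatError(f"{annotation_path}: annotation lacks a {col!r} column")
    annot = annot.set_index("sample")
    missing = [s for s in mat.columns if s not in annot.index]
    if missing:
        raise FormatError(
            f"{matrix_path}: samples absent from annotation: {missing[:5]}"
        )

    n_dup = int(mat.index.duplicated().sum())
    if n_dup:
        if collapse == "max_mean":
            # select by row position: idxmax on a duplicated index is ambiguous
            chosen = (
                pd.DataFrame({"gene": mat.index,
                              "pos": np.arange(len(mat)),
                              "mean": mat.mean(axis=1).to_numpy()})
                .sort_values(["gene", "mean"], kind="stable")
                .groupby("gene", sort=False)
                .tail(1)
                .sort_values("pos")
            )
            mat = mat.iloc[chosen["pos"].to_numpy()]
        else:
            mat = mat.groupby(level=0, sort=False).mean()
        log.info("%s: collapsed %d duplicate gene rows (%s)", matrix_path, n_dup, collapse)

    cov_cols = [c for c in annot.columns if c != "group"]
    covariates = annot[cov_cols] if cov_cols else None
    return ExpressionStudy(
        name=name or matrix_path.stem,
        genes=list(mat.index),
        samples=list(mat.columns),
        values=mat.to_numpy(dtype=float),
        groups=annot["group"],
        covariates=covariates,
    )


def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     annotation_path: str | Path, rng_seed: int | None = None) -> None:
    matrix_path = Path(matrix_path)
    with matrix_path.open("w") as fh:
        fh.write(_provenance(rng_seed))
        study.frame().to_csv(fh, sep="\t", index_label="gene")
    annot = pd.DataFrame({"group": study.groups})
    if study.covariates is not None:
        annot = annot.join(study.covariates)
    with Path(annotation_path).open("w") as fh:
        fh.write(_provenance(rng_seed))
        annot.to_csv(fh, sep="\t", index_label="sample")
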