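"""Per-study differential expression and cross-study concordance.

Differential expression between two sample groups uses a per-gene one-way
ANOVA F-test (equivalent to a two-sided equal-variance t-test for two
groups, F = t^2), with a direction (up/down) taken from the sign of the
case-minus-control mean. Categorical covariates, when supplied, are
removed first by subtracting each covariate level's mean from the values
(residualisation). Sample quality control flags outliers in principal-
component score space.

The concordance rule integrates several comparisons of the same biological
contrast: a gene counts as expression-supported "up" if it is significantly
up-regulated in at least ``min_support`` of the comparisons (and likewise
"down"); genes qualifying in both directions are conflicting and excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netio import ExpressionStudy

log = logging.getLogger("netprio.expression")

__all__ = ["DEStudyResult", "ConcordanceTable", "de_anova", "pca_outliers", "concordance"]


@dataclass
class DEStudyResult:
    """Per-gene F, p, direction and significance flag for one comparison."""

    study: str
    comparison: tuple[str, str]  # (case label, control label)
    table: pd.DataFrame  # index: gene; columns: F, p, direction, significant
    alpha: float = 0.05

    def flagged(self, direction: str) -> set[str]:
        t = self.table
        return set(t.index[(t["significant"]) & (t["direction"] == direction)])


def _residualise(values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Subtract per-level means of each categorical covariate, sequentially."""
    out = values.astype(float).copy()
    for col in covariates.columns:
        for level in covariates[col].unique():
            cols = np.nonzero((covariates[col] == level).to_numpy())[0]
            if cols.size:
                out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True)
    return out


def de_anova(
    study: ExpressionStudy,
    comparison: tuple[str, str],
    alpha: float = 0.05,
    use_covariates: bool = False,
    exclude_samples: Sequence[str] = (),
) -> DEStudyResult:
    """One-way per-gene F-test between the two groups of ``comparison``.

    Genes constant across all analysed samples get F = 0, p = 1 by
    convention. ``exclude_samples`` (e.g. QC outliers) are removed before
    testing; each group must retain at least two samples.
    """
    case, control = comparison
    excluded = set(exclude_samples)
    keep = [i for i, s in enumerate(study.samples) if s not in excluded]
    samples = [study.samples[i] for i in keep]
    values = study.values[:, keep]
    groups = study.groups.loc[samples]
    if use_covariates and study.covariates is not None:
        values = _residualise(values, study.covariates.loc[samples])

    ia = np.nonzero((groups == case).to_numpy())[0]
    ib = np.nonzero((groups == control).to_numpy())[0]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"comparison {comparison} needs >=2 samples per group "
            f"(got {len(ia)} vs {len(ib)})"
        )
    a, b = values[:, ia], values[:, ib]
    n1, n2 = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    grand = np.concatenate([a, b], axis=1).mean(axis=1)
    ss_between = n1 * (mean_a - grand) ** 2 + n2 * (mean_b - grand) ** 2
    ss_within = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df1, df2 = 1, n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    # constant genes (no variance anywhere): F = 0, p = 1 by convention
    total_ss = ss_between + ss_within
    const = total_ss <= 1e-300
    f = np.where(const, 0.0, f)
    p = np.where(const, 1.0, p)
    # zero within-group variance with a real difference: F -> inf, clamp p
    p = np.clip(p, 1e-300, 1.0)
    f = np.where(np.isfinite(f), f, np.inf)

    direction = np.where(mean_a - mean_b >= 0, "up", "down")
    table = pd.DataFrame(
        {
            "F": f,
            "p": p,
            "direction": direction,
            "significant": p <= alpha,
        },
        index=pd.Index(study.genes, name="gene"),
    )
    return DEStudyResult(study=study.name, comparison=comparison, table=table, alpha=alpha)


def pca_outliers(
    study: ExpressionStudy,
    n_components: int = 3,
    k_sd: float = 4.0,
) -> list[str]:
    """Samples far from the centroid in top principal-component score space.

    Distances are measured in the first ``n_components`` PC scores and
    scaled by a robust standard deviation (1.4826 * median absolute
    deviation); samples beyond ``k_sd`` robust SDs are flagged. With zero
    spread (e.g. identical samples) nothing is flagged.
    """
    if len(study.samples) < 3:
        raise ValueError("need >= 3 samples for outlier screening")
    x = study.values.T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    n_comp = min(n_components, min(x.shape) - 1)
    if n_comp < 1 or not np.isfinite(k_sd):
        return []
    # SVD-based PCA scores
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]
    dist = np.linalg.norm(scores - scores.mean(axis=0, keepdims=True), axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    scale = 1.4826 * mad
    if scale <= 1e-12:
        return []
    flagged = [study.samples[i] for i in np.nonzero(dist - med > k_sd * scale)[0]]
    if flagged:
        log.info("%s: flagged %d PCA outlier samples: %s", study.name, len(flagged), flagged)
    return flagged


@dataclass
class ConcordanceTable:
    """Per-gene direction support counts across comparisons of one contrast."""

    contrast: str
    n_comparisons: int
    min_support: int
    table: pd.DataFrame  # index gene; columns support_up, support_down, status
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    conflicting: list[str] = field(default_factory=list)


def concordance(
    results: Sequence[DEStudyResult],
    contrast: str = "C1",
    min_support: int | None = None,
) -> ConcordanceTable:
    """Direction-consistent support across comparisons.

    A gene passes "up" iff significantly up-regulated in >= ``min_support``
    comparisons, "down" analogously; genes passing both ways are excluded
    and reported as conflicting. ``min_support`` defaults to a majority of
    the comparisons (e.g. 3 of 5, 2 of 3, 2 of 2).
    """
    if not results:
        raise ValueError("no differential-expression results supplied")
    n = len(results)
    if min_support is None:
        min_support = n // 2 + 1
    if not 1 <= min_support <= n:
        raise ValueError("min_support must be between 1 and the number of comparisons")

    genes = sorted(set().union(*(set(r.table.index) for r in results)))
    support_up = pd.Series(0, index=genes)
    support_down = pd.Series(0, index=genes)
    for r in results:
        for g in r.flagged("up"):
            support_up[g] += 1
        for g in r.flagged("down"):
            support_down[g] += 1

    pass_up = support_up >= min_support
    pass_down = support_down >= min_support
    conflict = pass_up & pass_down
    status = np.where(
        conflict, "conflict",
        np.where(pass_up, "up", np.where(pass_down, "down", "none")),
    )
    table = pd.DataFrame(
        {"support_up": support_up, "support_down": support_down, "status": status},
        index=pd.Index(genes, name="gene"),
    )
    up = sorted(table.index[(table["status"] == "up")])
    down = sorted(table.index[(table["status"] == "down")])
    conflicting = sorted(table.index[(table["status"] == "conflict")])
    if conflicting:
        log.info("contrast %s: %d genes conflict in direction and are excluded",
                 contrast, len(conflicting))
    return ConcordanceTable(
        contrast=contrast,
        n_comparisons=n,
        min_support=min_support,
        table=table,
        up=up,
        down=down,
        conflicting=conflicting,
    )
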