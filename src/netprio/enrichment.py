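"""Hypergeometric pathway enrichment with Benjamini-Hochberg FDR control.

For a query gene set of size n drawn from a universe of size N, a pathway
with K members in the universe, and an overlap of k genes, the enrichment
p-value is the hypergeometric upper tail P(X >= k). p-values are corrected
across all tested pathways by the BH step-up rule; by default every pathway
with at least two universe members is tested (including those with zero
overlap), so the correction is not biased by a k >= 1 pre-filter — that
filter is display-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .netio import GeneSetCollection

log = logging.getLogger("netprio.enrichment")

__all__ = ["hypergeom_upper_p", "bh_fdr", "enrich"]


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); k=0 gives exactly 1.

    Computed in log space internally (scipy survival function), stable for
    universes up to ~1e6.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    q_threshold: float = 0.05,
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` in each gene set.

    Sets are trimmed to the universe; sets with fewer than ``min_set_size``
    surviving members are skipped. Query genes outside the universe are
    dropped with a warning. BH correction runs over every tested set. The
    returned table (one row per tested set, ascending p) carries columns
    set_id, description, k, K, n, N, p, q, significant.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        log.warning("%d query genes outside the universe dropped", len(stray))
    q_genes = query & universe
    n = len(q_genes)
    N = len(universe)

    rows = []
    for set_id in sorted(sets.sets):
        desc, members = sets.sets[set_id]
        trimmed = members & universe
        if len(trimmed) < min_set_size:
            continue
        k = len(q_genes & trimmed)
        K = len(trimmed)
        rows.append((set_id, desc, k, K, n, N, hypergeom_upper_p(k, K, n, N)))
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "description", "k", "K", "n", "N", "p", "q", "significant"]
        )
    table = pd.DataFrame(rows, columns=["set_id", "description", "k", "K", "n", "N", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] <= q_threshold
    table = table.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    return table
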