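# Methods

This note describes the statistical and algorithmic choices behind each
pipeline stage, the parameter defaults, and the synthetic benchmark the
package is validated against.

## Seed interactome

The interactome is the subnetwork around the input seed genes: the seeds
found in the background edge list plus their direct interaction partners.
By default only **seed-incident edges** are kept
(`include_neighbor_edges=False`); the full induced subgraph (which also
keeps neighbour–neighbour edges) is available behind the flag.

Rationale for the default: curated PPI databases are hub-rich, so the
induced subgraph over first neighbours pulls in a large number of edges
between generic high-degree proteins that have no direct relationship to
the seeds. Those connector hubs then dominate any degree- or
betweenness-based ranking and displace the disease-relevant genes from the
top of the list. Keeping seed-incident edges yields interactomes with
roughly 1.5–2 edges per node — star-like neighbourhoods around the seeds —
in which centrality reflects seed connectivity rather than database
ascertainment. On the planted benchmark this choice is what makes the
downstream recovery target attainable (sensitivity ≈ 0.9 versus ≈ 0.6 for
the induced subgraph).

Missing seeds (not present in the edge list) are recorded, not fatal; a
seed list with **no** matches is an error.

## Node ranking and the minimal essential network (MEN)

Every interactome node receives an unnormalised betweenness centrality
(Brandes' algorithm, unordered source–target pairs) and a degree. Each
metric is converted to a descending competition rank (ties share the
minimum rank) and the two ranks are summed; smaller is more central. The
MEN retains the top `ceil(retention_fraction × N)` nodes at the default
`retention_fraction = 0.10`. Ties at the retention boundary are resolved by
higher degree, then higher betweenness, then ascending symbol, so the MEN
is deterministic. A `union` mode (top 10% by either metric) is exposed as
an alternative.

For a 2,479-node interactome the 10% rule retains exactly 248 genes — the
convention `scripts/acceptance.py` checks.

## Degree-matched permutation test

The test asks whether the seed genes are more connected **to each other**
than expected for genes of the same connectivity. Nodes of the background
network are grouped into degree bins: exact-degree classes are merged
upward (ascending degree) until every bin holds at least `bin_min = 10`
nodes. Each permutation replaces every seed with a uniform
without-replacement draw from its own bin, and recomputes the statistics:

- **network-level**: the number of edges with both endpoints in the seed
  set;
- **per-seed**: the number of seed-incident edges at each (replacement)
  position.

P-values use the add-one estimator `p = (1 + #{null ≥ observed}) / (R + 1)`
with `R = n_permutations` (default 10,000), so the smallest attainable
p-value is `1/(R+1)` and the estimator is never zero. The per-seed
statistic is a small integer, so its permutation p-values are discrete and
conservative; the network-level statistic has enough support to be
calibrated (null rejection rate at α = 0.05 sits inside the 3-SE binomial
band in the acceptance suite).

The engine builds a dense boolean adjacency matrix once and evaluates each
permutation as a submatrix sum, which makes 1,000 permutations on a
2,000-node network take well under a second.

## Complex detection (MCODE-style)

Each vertex is weighted by `k × density` of the highest k-core of its
closed neighbourhood. Complexes are grown from the highest-weighted
unvisited vertex: the complex is the seed vertex plus those **direct
neighbours** whose weight exceeds `(1 − vwp)` times the seed weight
(`vwp = 0.2`). Expansion is deliberately single-level — recursive expansion
chains through bridge vertices and merges well-separated dense regions
(two four-cliques joined by one edge would collapse into a single
cluster, which is exactly the structure a complex detector should keep
apart). The optional *haircut* (default on) removes members with fewer
than two within-complex edges; trimmed vertices return to the unvisited
pool so a neighbouring complex can claim them. Complexes smaller than
`min_size = 3` are dropped; the score is `density × size`.

One consequence worth knowing: a moderately dense planted module
(within-module edge probability 0.3) is reported as several small,
module-pure complexes rather than one — single-level expansion trades
completeness of any one cluster for purity, which is the right trade for
prioritisation.

## Spectral community partitioning

The MEN is partitioned by leading-eigenvector modularity bisection: for a
(sub)graph the generalised modularity matrix `B_g = B − diag(B·1)` is
formed, its leading eigenvector splits the nodes by sign, and the split is
accepted only if the modularity gain `ΔQ = sᵀB_g s / 4m` is positive;
accepted halves are bisected recursively. Eigenvector sign is fixed
deterministically (first non-zero entry positive). Connected components
are partitioned independently. Kernighan–Lin refinement sweeps are not
applied; the tests bound the achieved modularity by an exhaustive search
over all partitions on small graphs rather than asserting optimality.

## Pathway enrichment

For a query set (the MEN, or one complex) and each gene set with at least
two members in the universe (all interactome nodes), the upper-tail
hypergeometric probability of the observed overlap is computed
(`scipy.stats.hypergeom.sf(k−1, N, K, n)`; `k = 0` gives p = 1 by
definition). Benjamini–Hochberg step-up q-values are computed across all
tested sets; significance is `q ≤ 0.05`. Query genes outside the universe
are dropped before testing.

## Differential expression and concordance

Per study, each gene gets a one-way ANOVA F-test between the two groups of
a comparison (vectorised; for two groups F = t² exactly). Direction is the
sign of (case mean − control mean); constant genes get F = 0, p = 1.
Categorical covariates can be removed by per-level mean residualisation
before testing, and a PCA-based sample QC (scores beyond `k_sd = 4`
MAD-robust standard deviations on the top components) can exclude outlier
arrays.

A gene is **concordant** for a contrast when it is significant
(`alpha_de = 0.05`) with the *same* direction in at least `min_support`
comparisons (default: a majority, `n//2 + 1` — e.g. 3 of 5, or both of 2).
Genes significant in both directions across comparisons are excluded as
conflicting and reported separately.

## Prioritisation

The final gene list is the intersection of three filters, so
`prioritised ⊆ candidates ⊆ MEN ∩ seeds` always holds:

1. in the MEN (topologically essential);
2. per-seed permutation p ≤ `alpha_perm = 0.05` (more connected than
   degree-matched chance);
3. concordantly differentially expressed in ≥ 1 contrast.

Output is sorted by ascending permutation p, ties by symbol. Each gene is
annotated with the MCODE complex containing it (complexes are disjoint by
construction), and every complex holding at least one prioritised gene is
reported with its own pathway enrichment.

## Synthetic benchmark

`netprio.synthetic` plants a full ground truth:

- **Network**: preferential attachment grown from an initial clique
  (`n = 2,000` nodes, `m = 2` edges per new node), giving the heavy-tailed
  degree distribution typical of PPI networks. What it does *not* emulate:
  date-hub correlation structure, study ascertainment bias, or edge
  weights/confidence scores.
- **Seed module**: 150 seed genes of which 30 form a module densified to
  within-module edge probability `p_within = 0.3` (background pairs are
  orders of magnitude sparser).
- **Pathways**: 50 random sets of 20–80 genes plus one designed set
  (`SET_PLANTED`) drawn from the module.
- **Expression**: per comparison, Gaussian noise (`noise_sd = 1`) with a
  ±`effect_size = 1.5` shift on the module genes at `n = 20 + 20` samples;
  the direction is fixed per gene per contrast, so comparisons within a
  contrast agree and the concordance rule has signal to find.

These defaults are the package's standard validation conditions, chosen to
be representative of a mid-sized microarray meta-analysis; they are fixed,
not fitted. Under them the end-to-end pipeline recovers ≥ 70% of module
genes at ≥ 90% precision (`tests/test_acceptance.py`), the permutation
null is calibrated, and the ANOVA null flag rate matches α.

## Reproducibility

One global `rng_seed` is split per stage with `numpy.random.SeedSequence`,
so stages are individually reproducible and independent of each other's
draw counts. Every output file carries the package version and seed;
`manifest.json` records per-stage counts, timings and a configuration
hash. All pipeline randomness lives in the permutation stage; rankings,
clustering, enrichment and DE are deterministic given the inputs.

## Problem sizes

The defaults target desk-scale runs: interactomes of 10²–10⁴ nodes,
10,000 permutations in seconds to a minute, exact betweenness up to a few
thousand nodes (O(nm); the dominant cost for large inputs). Approximate
betweenness, weighted edges, and overlapping complexes are out of scope.
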