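# Methods

## Scope

`senskin` implements a signed-signature workflow for detecting cellular
senescence in human skin transcriptomics: a packaged skin-specific
senescence gene set, a per-cell composite score, per-cell-type condition
contrasts, inter-gene correlation clustering on pseudobulk expression,
phenotype-permutation gene set enrichment (GSEA), Wilcoxon rank-sum
differential expression, and hypergeometric over-representation analysis
(ORA). A negative-binomial synthetic-data generator reproduces the
statistical structure the workflow assumes, so every stage is testable
end-to-end without external downloads.

## The signature

The packaged set contains 165 gene symbols: 164 expected to rise in
senescent skin cells (SASP factors, stress-response and immune genes,
IGF-binding proteins, metallothioneins, matrix remodelers) and one expected
to fall (`LMNB1`, lamin B1, whose loss is a widely used senescence marker).
The set ships as a plain TSV (`src/senskin/data/senskin_genes.tsv`, one
symbol per line with an up/down column) and a checksum test guards against
transcription drift. Symbols are matched case-insensitively with no
alias/HGNC resolution: deterministic behaviour was preferred over dependence
on an external symbol database.

Because standard GMT has no direction field, signed sets are serialized as
`NAME_UP` / `NAME_DN` line pairs; a suffix-free line is an unsigned (all-up)
set. The round-trip is exact.

## Composite score

For a cell `c` with per-gene z-scores `z(c, g)` (genes standardized across
cells after library-size log-normalization `ln(1 + 1e4 * x/total)`),

```
score(c) = mean_{g in U} z(c, g) - mean_{g in D} z(c, g)
```

where `U`/`D` are the up/down signature genes present in the matrix.
Genes absent from the data are excluded and the divisors shrink accordingly
(with a logged warning); when no down gene is present the second term is 0.
Z-scores use the sample standard deviation (`ddof=1`, switchable); constant
genes become all-zero columns. Standardization is performed jointly over all
cells.

Note that the single down gene carries the same weight as the mean of all
164 up genes, so its measurement noise contributes substantially to the
score variance — a property of the published formula, not of this
implementation.

### Condition contrasts

Per cell type, scores in the two conditions are compared with the unpaired
Wilcoxon rank-sum (Mann–Whitney U) test: exact distribution when both
groups have ≤ 25 tie-free observations, mid-rank normal approximation with
continuity correction otherwise. A signed-rank option exists for genuinely
paired designs, but the default is unpaired because condition groups of
cells are unpaired. P-values are Bonferroni-adjusted across cell types by
default (Benjamini–Hochberg optional); direction (up/down) is assigned from
the difference of medians only for adjusted-significant cell types. Cell
types with fewer than 2 cells in either condition are flagged
`insufficient` and not tested.

## Correlation clustering

The signature-characterization recipe: aggregate cells to pseudobulk
(per-sample sums of raw counts by default; the grouping key is exposed
because sample vs. sample-by-cell-type aggregation is a genuine choice),
compute each gene's adjusted Fisher–Pearson skewness
(`G1 = g1 * sqrt(n(n-1))/(n-2)`; the uncorrected `g1` is an option since
the count of "skewed" genes can depend on the estimator), and if any gene
exceeds skewness 2, `ln(1+x)`-transform the matrix. The default transforms
the *whole* matrix when triggered (the plain reading of the recipe); a
per-gene mode is provided, and the mode is an explicit argument rather than
a silent heuristic. Genes are then standardized and Pearson-correlated
(Spearman optional); zero-variance genes correlate 0 with everything and
are flagged.

Complete-linkage agglomeration runs on distance `d = 1 - r` — not
`1 - |r|`, preserving the sign structure of the correlation heatmap — and
the tree is cut into `k` clusters (`k = 5` by default; no automatic `k`
selection is attempted). The merge loop is delegated to
`scipy.cluster.hierarchy`; an independent naive O(n³) agglomeration oracle
in the test suite verifies merge heights and partitions on random
correlation matrices. Ties in merge distances are resolved
deterministically for a fixed gene order (they have probability zero for
continuous expression data). Cluster ids are renumbered 1..k along the
dendrogram leaf order so each cluster is a contiguous block in reports.

## GSEA engine

"Default" classic GSEA behaviour is pinned explicitly rather than inherited
from an external tool:

* **Ranking metric** — signal-to-noise
  `s2n = (mu_A - mu_B)/(sd_A + sd_B)` with population sds, each floored at
  `0.2 * |mean|` and at 0.2 outright when the mean is 0. Requires ≥ 3
  samples per group.
* **Enrichment score** — weighted KS running sum, hit increments
  `|metric|^p / sum_hits |metric|^p` with `p = 1`, miss decrements
  `1/(N - N_hits)`; ES is the running value at the maximum absolute
  deviation; the leading edge is the hits at or before (after, for negative
  ES) the peak. When all hit weights are zero the increments fall back to
  uniform.
* **Null** — permutation of phenotype labels (never genes), seeded;
  `n_perm = 1000` by default. The batch of permuted metrics is computed by
  one matrix product per simulation, so the default test scales are cheap.
* **NES / p / FDR** — sign-stratified: NES = ES / mean |same-sign null ES|;
  nominal p is the same-sign tail fraction with an add-one correction (so
  p ≥ 1/(n_perm+1), never 0); FDR q is the ratio of null and observed
  normalized tail fractions on the matching sign side, clipped to [0, 1].
  A set with no same-sign null ES gets NaN NES/p/q with a warning rather
  than a coerced value.
* Gene identifiers are used as-is (no probe collapse).

The engine was cross-checked against an independent brute-force running-sum
oracle (500 random instances) and against `gseapy`'s prerank ES on random
instances; `gseapy` is a test-only dependency, never the implementation.

## Differential expression

Per-gene Wilcoxon rank-sum on log-normalized values. ln-fold-change uses
the shifted-mean convention
`ln(mean(expm1 x_A)+1) - ln(mean(expm1 x_B)+1)` so the customary 0.25
natural-log cutoff applies (a plain difference of log-means is an option).
Bonferroni adjustment over tested genes; a gene "passes" when
`|ln_fc| >= 0.25` and adjusted `p < 0.05` (both cutoffs are parameters).

## ORA

Hypergeometric upper-tail `P(overlap >= k)` for a query of `n` genes
against a pathway of `K` genes in a universe of `N`, with
Benjamini–Hochberg FDR across pathways (threshold 0.05 by default). Query
genes outside the universe are dropped with a warning. Pathway collections
are user-supplied GMT files; no pathway database is bundled.

## Synthetic data

The generator emulates the two study designs the workflow targets — a
two-condition single-cell experiment (UV-protected vs UV-exposed skin) and
a young-vs-old bulk cohort — with the minimal generative model matching
scRNA-seq overdispersion: negative-binomial counts
(`var = mu + alpha*mu^2`, Gamma–Poisson sampling), gene-specific log-means
`~ N(-2, 1)`, per-cell lognormal size factors (`sigma = 0.3`), and
cell-type identity expressed as 4-fold marker boosts on a random 5% of
genes. Defaults: six skin cell types (fibroblast, keratinocyte, T cell,
pericyte, vascular endothelial, macrophage) with 200 cells per condition
each and 5 donors per condition; bulk mode uses 24 samples per group (the
design of the chronological-aging cohort the method is aimed at) with
dispersion 0.1 and deeper counts.

The senescence program is planted on the natural-log mean scale — up-genes
shifted by `+effect_delta`, `LMNB1` by `-down_delta` — in a configurable
fraction of condition-2 cells per cell type (`affected_fraction`, scalar or
per-cell-type mapping; default 0.3, treating senescent cells as a minority
population). Log-scale injection makes `effect_delta` directly comparable
to the ln-fold-change cutoff used downstream. Ground-truth flags are
emitted per cell so tests can compute recovery without re-deriving truth.
Fixed config (including its seed) gives bit-identical output.

What the generator does **not** model: batch effects and dataset
integration, doublets, ambient RNA, realistic cell-type proportions, or
gene–gene co-expression beyond the planted program and shared size
factors. Passing tests therefore demonstrate statistical correctness and
calibration of the pipeline under the stated generative model, not
robustness to real-data artefacts.

## Verification experiments and problem sizes

The test suite verifies, at sizes chosen to keep the default run fast:

* null calibration of the GSEA nominal p (400 simulated null cohorts,
  200 permutations each, 300 background genes) and of the per-cell-type
  rank test (100 null simulations), both required to reject at 5% within
  the binomial confidence band;
* exact recovery of a program planted wholesale in 2 of 6 cell types at
  `effect_delta = 0.5` (100 replicate experiments, 500 background genes,
  Bonferroni α = 0.05), required in ≥ 90% of replicates — residual
  failures are the expected family-wise false positives. With partial
  penetrance (`affected_fraction = 0.3`) at `effect_delta = 1.0` the exact
  recovery rate sits near this 90% boundary: the single down gene's noise
  contribution and minority penetrance make that regime power-limited — a
  known limitation of the score rather than of the tests;
* oracle equivalence of the ES computation (500 random instances) and of
  complete linkage (100 random matrices up to 8 genes);
* exact small-sample agreement of the rank test with exhaustive
  enumeration and of ORA with closed-form hypergeometric tails.

`scripts/acceptance.py` re-runs the same experiments from scratch at the
sizes printed in its output (`n` fields) and writes the computed quantities
as JSON.

## Known limitations

* Symbol matching is string-based; signatures and expression data must
  share a namespace.
* The pseudobulk grouping used upstream of correlation clustering is a
  user decision; different groupings give different correlation structure.
* GSEA FDR with a single gene set reduces to the normalized-null tail
  fraction; with few sets the sign-stratified FDR estimate is coarse,
  exactly as in the reference procedure.
* Dense matrices are materialized for scoring; the intended scale
  (10³–10⁵ cells, ≤ a few 10⁴ genes) fits comfortably in memory, but the
  implementation is not out-of-core.
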