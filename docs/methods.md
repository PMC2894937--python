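# Methods

This note documents the models, algorithms and numerical choices behind
`ctdnet`, and what the synthetic generators do and do not emulate.

## Regulation calling

Differential expression is a pure fold-change criterion on per-gene
mutant/control ratios: up if ratio ≥ `high_cut` (default 2.0), down if
ratio ≤ `low_cut` (default 0.5), else unchanged. Ratios at exactly a cutoff
are called DE by default (`inclusive=True`); the choice is exposed because
"cutoff" conventions differ between analysis tools. Ratios (not log-ratios)
are the canonical unit; `ExpressionTable.from_log2` and the `--log2-input`
flag convert log2 input. Replicate averaging and normalization are assumed
upstream: the table carries one positive finite ratio per gene, and a
duplicated gene is a hard error rather than something to silently average.

There is deliberately no statistical DE test (no moderated t-statistics, no
variance model): the calling criterion the pipeline formalizes is
fold-change only, and the downstream network logic needs only the
up/down/unchanged partition.

DE genes with no functional annotation cannot seed a category subnetwork
and are removed by `filter_annotated`, which returns them as an explicit
exclusion list. Unannotated *non*-DE genes are retained in the unchanged
set — they never enter network construction, and dropping them would
silently shrink the enrichment universe.

## Enrichment

Overrepresentation of DE genes in a category uses the hypergeometric upper
tail P(X ≥ k) with universe size N, category size K, draw size n and
overlap k, computed via `scipy.stats.hypergeom.sf` (numerically stable in
the far tail). The default universe is every gene in the expression table
(`all_array_genes`), matching the whole-annotation default of standard GO
tools; `annotated_only` restricts to annotated genes.

Multiple testing uses the Benjamini–Hochberg step-up procedure
(`statsmodels`, `fdr_bh`), with flags `p_adj ≤ alpha` (default 0.05).
Every category with at least one member in the universe counts as a tested
hypothesis; categories with zero DE overlap are then dropped from the
output table only. Annotation is treated as flat memberships — no GO-graph
parent-term propagation is performed, but pre-propagated annotation can be
supplied through the same interface.

Calibration is verified by simulation: under a global null (DE drawn
uniformly), the family-wise rate of reporting any significant category
stays near alpha; a planted category whose members enter the DE set at 10×
the background rate is detected with power ≥ 0.95 (see
`scripts/acceptance.py`).

## Anchored subnetwork pruning

The pipeline builds, per phenotype-related GO category, the
direct-interaction network of the DE genes annotated to it: nodes are the
seeds plus their interaction partners, edges are the edges *incident to a
seed*. Edges among non-seed partners are excluded by default — this is the
"first-order interactions of a query list" convention — with an
`include_neighbor_edges` flag for the induced-subgraph reading. Merging
networks is node/edge union with per-edge pooling of evidence tags;
evidence tags never affect topology, only reporting. Graphs are undirected
and self-interactions are excluded by default (they cannot lie on an
anchor→DE path).

Pruning formalizes "only contiguous links retained" as *simple-path
membership*: with admissible set A = {anchor} ∪ E ∪ D (E the bridge
interactors, D the DE genes present), take the induced subgraph on A, keep
the anchor's connected component, and retain exactly the nodes lying on at
least one simple anchor→DE path. This is the weakest reading that
guarantees every retained node participates in an anchor↔DE connection; it
degenerates to the lone anchor when no DE gene is reachable. A node in both
E and D takes the DE role (display reserves the interactor color for
bridges with no expression change).

Simple-path membership is computed exactly via the block-cut tree: the
vertices on some simple s–t path are the union of the biconnected
components along the unique tree path between s and t. The implementation
is validated against exhaustive `all_simple_paths` enumeration on hundreds
of random graphs of ≤ 12 nodes (100% node-set agreement required).

Strict mode admits only the curated evidence-interactor list as bridges;
relaxed mode admits every first interactor of the anchor, optionally
restricting the DE endpoints to a curated phenotype-evidence gene list
(`de_filter`). When the evidence list is a subset of the anchor's
neighborhood — as it is by construction in real use — strict results are
monotonically contained in relaxed results.

## DNA-content gating

Brackets are anchored on the strongest G1 signal peak (SSP) with marker
range MR = SSP/4: G1 = [SSP−MR, SSP+MR], G2 = [2·SSP−MR, 2·SSP+MR], S the
open interval between them; events below G1 are reported as sub-G1 debris
and events beyond G2 as ">2C" content rather than silently dropped. Closed
G1/G2 brackets and an open S interval make the five regions a partition, so
percentages sum to 100 exactly; a merged "2C and greater" figure
(`pct_2c_and_greater`) is also exposed. Brackets are scale-equivariant:
rescaling events and SSP together leaves percentages unchanged.

SSP estimation (the original workflow located it interactively) is a
histogram mode: 256 equal-width bins over [0, max], a centered
moving-average smoother of width 5 (edge-normalized), global maximum with
ties broken toward the lower channel; a constant event vector returns that
constant. All three are configurable. For time courses a `fixed_ssp` can be
imposed so gating stays consistent across samples.

## Synthetic generators

`generate_study` emulates the study conditions: a 6,221-gene array universe
with 325 up- and 493 down-regulated genes, 277 DE genes lacking annotation,
three phenotype categories (chromosome segregation; cell wall and membrane;
cell cycle and repair) among 24 categories of 100–500 members, an anchor of
degree 30 with 8 evidence-qualified interactors of which one connector (the
mediator-like role) bridges the anchor to the planted DE genes of all three
categories. Because random size-based category sampling cannot guarantee
covering every annotated gene, any uncovered annotated gene is appended to
one random category (sizes may slightly exceed the configured range).

Planting is margin-safe: planted up/down log2-ratios are Normal(±2, 0.3)
clipped beyond ±1.05 and background ratios clipped strictly inside ±0.95,
so the called sets equal the planted sets exactly and all recovery tests
are deterministic. The background interactome is a configuration-model
graph with a power-law-ish degree sequence (exponent 2.5, minimum degree 1,
cap 60); planted DE genes and evidence interactors are excluded from it and
wired only through curated edges (anchor star, connector→DE, and cosmetic
edges into inadmissible background nodes), which is what makes connector
recovery exact rather than probabilistic. The generator does **not**
attempt to reproduce the real yeast interactome, SGD annotation or the
actual deposited ratios; passing recovery tests therefore demonstrates
algorithmic correctness under known ground truth, not robustness to the
noise structure of real arrays or databases.

`simulate_population` draws, per cell, a cell-cycle phase with *exact*
largest-remainder counts at the configured fractions (default 60/20/20 —
the exponential-growth control profile), a DNA content (1×, S-range×, or 2×
the 1C signal, default 200), a ploidy multiplier (1 for euploid; for
aneuploid cells from {1.5, 2, 2.5, 3} with geometric weights 8:4:2:1), and
multiplicative Gaussian stain noise (default CV 5%). The aneuploid
probability at growth cycle c is 1 − (1 − r)^min(c, c_eq) with per-cycle
rate r = 0.08 and equilibrium cycle 11, emulating continuous DNA-content
drift that plateaus after cycle 11 through cycle 20. S-phase content is
drawn uniformly on (1.25, 1.75)×1C — exactly the open interval between the
G1 and G2 brackets — rather than the full (1, 2) range, so that noiseless
populations gate back to their phase fractions exactly; the range is a
config field. Exact phase counts and the RNG seeding scheme (one integer
seed plus the cycle index) make every event vector bit-reproducible.
Doublet exclusion, debris modeling, compensation and instrument saturation
are not simulated; events are assumed singlet-gated upstream.

## Problem sizes and tolerances

Validation uses sizes chosen to make the checks exact or statistically
well-powered while staying quick: 500 random graphs (≤ 12 nodes) for the
pruning oracle; the full (N ≤ 30, K, n, k) lattice (≈ 87,000 tuples) for
the hypergeometric tail at 1e-12; 1,000 random p-vectors for BH; 1,000 null
and 200 planted enrichment replicates on a 2,000-gene universe with 50
categories; the full 6,221-gene study for end-to-end recovery; 50 seeds ×
21 cycles × 4,000 cells for drift monotonicity (mean-level slack 0.5
percentage points, ≈ 2.5× the standard error of the 50-seed mean; plateau
deviation bound 1.0 point). The 5%-CV G1-recovery tolerance of ±2
percentage points covers binomial sampling error plus bracket leakage of
noisy S-phase events into the adjacent closed brackets.

## Known limitations

- Gene identity is name-based (case-insensitive, optional alias table);
  there is no identifier-type reconciliation beyond the alias map.
- Evidence-class filtering (physical vs genetic interactions) is left to
  the caller; tags are preserved but nothing is filtered by default.
- The enrichment module does not parse OBO files or traverse the GO DAG.
- Curation of which anchor interactions are CTD-specific is an input, not
  something the package infers.
- FCS binary files are not parsed; event vectors arrive as plain CSV.
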