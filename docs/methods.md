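# Methods

## Model

The package treats a tumour sample as an expression-weighted PPI graph. Node
*i* with concentration C_i ≥ 0 (normalized transcript units, used as a proxy
for protein abundance) and neighbour concentrations C_j has potential
G_i = C_i ln(C_i / (Σ_j C_j + C_i)), a unitless, Gibbs-like quantity that is
0 for an unexpressed or isolated node and strictly negative otherwise. The
sample's state is the total G = Σ_i G_i. In-silico repression of gene g sets
C_g to 0; the disruption ΔG(g) = G_after − G_before is non-negative because
G_g rises to 0 and every neighbour's denominator shrinks. Genes are ranked by
mean ΔG across samples (unweighted; ties broken lexicographically by symbol so
rankings are reproducible).

Boundary conventions, chosen as the formula's continuous limits and asserted
by tests: G_i = 0 when C_i = 0 (x ln x → 0) and when the neighbour sum is 0
(ratio exactly 1). Natural logarithms throughout. Repressions are scored
one-at-a-time against the common unrepressed baseline, never cumulatively.

ΔG is computed incrementally: only the repressed gene and its direct
neighbours can change, giving O(|E|) for a full per-gene sweep
(`batch_delta_g`). Each local term is mathematically ≥ 0 and is clamped at 0
against floating-point rounding, so the sign invariant ΔG ≥ 0 holds exactly.
The incremental path is verified against a rebuild-and-recompute oracle (per
node, 100 random networks up to n = 200) at 1e−9 relative tolerance; the
oracle sums per-node potential differences, which cancels untouched nodes
exactly and keeps the comparison free of global-sum cancellation.

## Null model

The null asks whether a gene's ΔG reflects the sample's specific wiring or
just its degree and expression. Each iteration rewires the graph by
degree-preserving double-edge swaps — two edges u–v, x–y chosen uniformly,
rewired to u–x, v–y, rejecting self-loops and duplicates — with
n_nodes × 100 *accepted* swaps (rejections are retried, so the amount of
randomization is independent of the rejection rate), leaves expression
unchanged, and recomputes ΔG for the scored genes (the top 50 by default).
The summary is the per-gene mean and sd over 1000 iterations with a two-sided
CI at level 1 − α/n_tests (α = 1e−4, Bonferroni over the genes scored). The
CI uses the normal approximation mean ± z·sd: practical iteration counts
cannot resolve 99.99% tails empirically, and mean/sd are the summary the
procedure computes anyway; an empirical-percentile mode is available
(`method="percentile"`) but not default. Observed means inside the closed
interval are flagged `inside_ci`.

Per-iteration seeds derive from the master seed via `numpy.SeedSequence`, so
identical seeds give bitwise-identical summaries; iterations are independent
and could run concurrently provided results are reduced in iteration order.

On a swap-degenerate graph (e.g. a triangle, where every proposal is
rejected) the retry budget (default 100 × n_swaps proposals) runs out; the
default is to return the graph randomized so far with a warning — degrees are
preserved regardless — while `strict=True` raises instead. This keeps
long null runs robust while making exhaustion detectable.

## miRNA and cocktail scoring

A miRNA→gene pair is trusted when supported by ≥ 2 prediction databases
(`min_sources`, inclusive); a miRNA's target set is the union of its retained
pairs. A single miRNA's disruption is Σ ΔG over its targets inside the scored
gene universe — by default every ranked gene, the maximum-disruption reading;
`--top-n` restricts the universe instead, and the choice is echoed in the run
manifest.

Cocktails model low-dose combination dosing: a gene hit by c distinct
cocktail members is repressed by A(c) = 0 for c ≤ min_multiplicity − 1
(default: c ≤ 1) and min(saturation, r·c) otherwise (defaults r = 0.2,
saturation 1), i.e. 40%/60% at two/three hits, complete repression at six.
The loss of a k-cocktail μ (k = 3 by default) is
L(μ) = Σ_{i∈I} A(c_i)·ΔG_i − Σ_{j∈J} A(c_j)·ΔG_j with J the top-k targets
(k = 10 by default) and I the housekeeping set. The two sums are independent
(a product-space reading would only rescale every loss by the other set's
size and cannot change the ranking). A(c)·ΔG scales the full-repression
disruption linearly rather than re-evaluating the potential at reduced
concentration; `exact_gene_effect` provides the exact re-evaluation for
comparison. Genes outside I ∪ J do not enter the loss. A gene in both sets
counts as a target only; housekeeping genes without a ΔG value (absent from
the ranked universe) are dropped with a logged tally. Multiplicity counts
distinct miRNAs, with no dose weighting.

Candidates are miRNAs hitting ≥ 2 of the top-k targets; all C(m, k)
combinations are enumerated exhaustively (the pre-filter keeps this
desk-scale) and ranked by ascending loss with a deterministic id-tuple
tie-break. The sensitivity grid re-ranks over r ∈ {0.1…0.5} ×
top-k ∈ {5, 10, 15}; it varies the slope r only, keeping the
minimum-multiplicity and saturation thresholds fixed, and reports cocktails
present in every cell's top 10. For fixed multiplicities below saturation the
loss is linear in r, so rankings are r-invariant until some gene saturates —
a property the tests exercise.

## Synthetic data

The generators emulate the statistical shape of the real inputs, not any
dataset's values: Barabási–Albert or power-law configuration graphs (sparse,
hub-heavy; named toys — star, cycle, complete, two-hub — carry the closed-form
oracles); log-normal expression (log-mean 2.0, log-sd 0.8) with a 15%
zero-inflation spike, replicates drawn as 5% log-normal perturbations of a
shared gene mean (replicate correlation > 0.9, matching the low
between-replicate variance of cell-line data); heavy-tailed per-miRNA target
counts (log-normal, mean 8, log-sd 0.8) with optional degree bias; a
housekeeping list taken from the most highly expressed genes. Zero-inflated
expression is bimodal (zero spike + expressed mass) while node potentials of
expressed genes spread continuously below zero — the qualitative contrast the
fixture tests assert.

The planted end-to-end scenario wires its miRNA panel against the *realized*
ΔG ranking (computed in-generator), so its guarantees hold for every seed: a
hub with half the nodes as neighbours and 10× the largest other concentration
is the rank-1 target; a selective miRNA covers ranks 1–3 with no housekeeping
targets; a promiscuous miRNA covers the two weakest top-10 targets plus most
of the housekeeping set; four fillers have pairwise-disjoint target pairs and
housekeeping picks inside the promiscuous miRNA's pool, so cooperative
housekeeping repression occurs only alongside it. Exhaustive enumeration then
places the selective miRNA in the best cocktail and the promiscuous one in
the worst. A decoy pair with a single supporting source checks the
min-sources filter.

What passing these tests shows — and does not. The fixtures validate the
mechanics (formulas, invariants, determinism, enumeration) and the
qualitative selectivity/promiscuity contrast. They do not reproduce any real
PPI topology, expression profile or miRNA mapping, so they say nothing about
which genes or miRNAs matter in any actual tumour.

## Problem sizes and numerics

Default test problem sizes are desk-scale by design: oracle equivalence uses
100 random networks of 12–200 nodes; the sign invariant samples > 1000 nodes;
the scaled-down null uses an n = 500 fixture with 50 genes × 100 iterations
at the full swap multiplier of 100. Comparisons use 1e−9 relative tolerance
where an exact oracle exists and exact equality for seed-determinism checks.
Wall-clock timings are logged rather than written to the run manifest so that
identical (inputs, config, seed) produce byte-identical output files.

## Known limitations

- mRNA concentration stands in for protein concentration; the potential is
  blind to post-transcriptional regulation.
- Predicted miRNA–target pairs are homology-based; shared binding sites make
  the additive per-miRNA repression assumption optimistic, and the linear
  A(c) slope is a modelling convenience (the sensitivity grid probes it).
- The PPI network is static and generic; tumour-specific rewiring is not
  modelled.
- The normal-approximation CI is symmetric even though ΔG null distributions
  can be skewed; the percentile mode trades tail resolution for shape.
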