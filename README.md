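# netpotential

Rank therapeutic gene targets — and cocktails of miRNAs to repress them — by
how much their loss would disrupt a tumour's cell-signalling network.

`netpotential` is aimed at computational/systems-biology groups designing
RNA-based combination therapy. It takes a protein–protein interaction (PPI)
network (BioGRID or STRING exports), a normalized gene-expression matrix for
one or more tumour samples, a miRNA → target mapping table, and a housekeeping
gene list, and produces: per-sample network potentials, a ΔG ranking of gene
targets with a degree-preserving permutation null, single-miRNA disruption
scores, and an exhaustive ranking of k-miRNA cocktails that reward cooperative
repression of top targets while penalizing cooperative repression of
housekeeping genes (a toxicity proxy).

## The model

Each node *i* of the PPI graph carries the sample's transcript concentration
*C<sub>i</sub>* (used as a proxy for protein concentration). Its **network
potential**, a Gibbs-like state measure, is

```
G_i = C_i · ln( C_i / (Σ_j C_j + C_i) )        (j over neighbours of i)
```

which is always ≤ 0; the network's total potential is G = Σ<sub>i</sub> G<sub>i</sub>.
**In-silico repression** of a gene sets its concentration to zero; the
resulting rise in total potential, ΔG ≥ 0, measures how much the network
depends on that gene, and genes are ranked by mean ΔG across samples. The
observed ΔG of the top genes is compared against a null built by rewiring the
graph with degree-preserving double-edge swaps (n·100 accepted swaps per
iteration, expression unchanged), summarized as mean ± z·sd with a
Bonferroni-corrected normal quantile (99.99% CIs by default).

A single miRNA's maximum disruption is the summed ΔG of its predicted targets
(pairs supported by ≥ 2 prediction databases). A **cocktail** μ of k miRNAs
given at low dose only represses genes hit by several of its members: a gene
hit by *c* distinct cocktail miRNAs loses the fraction

```
A(c) = 0 for c ≤ 1;   A(c) = min(1, 0.2·c) otherwise
```

of its expression (40% at two hits, 60% at three). Cocktails are scored by the
loss

```
L(μ) = Σ_{i ∈ I} A(c_i)·ΔG_i  −  Σ_{j ∈ J} A(c_j)·ΔG_j
```

over the housekeeping set I and the target set J (the top-k genes by mean ΔG);
the most negative loss is best. All C(m, k) combinations of the pre-filtered
candidates (miRNAs hitting ≥ 2 of the top targets) are enumerated.

## Worked example

Everything runs on synthetic data with the statistical shape of the real
inputs (hub-heavy graph, zero-inflated log-normal expression, promiscuous
miRNA mappings), so no downloads are needed:

```bash
netpotential simulate --seed 3 --out demo_bundle
cat > demo_config.yaml <<EOF
network: demo_bundle/network.tsv
expression: demo_bundle/expression.tsv
target_map: demo_bundle/target_map.tsv
housekeeping: demo_bundle/housekeeping.txt
iterations: 100
null_top: 10
outdir: demo_out
seed: 3
EOF
netpotential run demo_config.yaml
```

`demo_out/ranked_targets.tsv` starts:

```
gene    rank  mean_delta_g  S1          S2
G0000   1     833.430307    828.376378  838.484236
G0011   2     55.702986     57.042479   54.363493
G0054   3     54.409628     52.430725   56.388532
```

The planted hub `G0000` dominates the ranking: repressing it raises the total
network potential (`total_potential.tsv`: −1442.6 for sample S1) by ~833,
fifteen-fold more than any other gene. `null_summary.tsv` shows its null CI
(672.0, 960.8) contains the observed value — a highly connected hub scores
high on ΔG for topological reasons alone, which is exactly what the null
model is there to flag. The cocktail table:

```
rank  mirna_1  mirna_2  mirna_3     loss        n_targets_hit  n_housekeeping_hit
1     MIR-F1   MIR-F2   MIR-SELECT  -355.653317 2              0
...
20    MIR-F1   MIR-F2   MIR-PROMISC  61.490549  0              4
```

The best cocktail pairs the selective miRNA with partners that co-target the
strongest targets and no housekeeping genes; the worst one cooperatively
represses four housekeeping genes and earns a positive (harmful) loss.

The same stages are available programmatically (`netpotential.rank_targets`,
`score_mirnas`, `rank_cocktails`, …) and as individual subcommands
(`build-network`, `potential`, `rank-targets`, `null`, `rank-mirnas`,
`rank-cocktails`).

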