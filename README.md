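# plastevo

Detecting the **evolution of gene-expression plasticity** from bulk RNA-seq
counts in a two-population thermal-acclimation design, together with the
co-expression and miRNA analyses that surround it. The motivating setting is
an invasive ectotherm expanding its range poleward: an ancestral southern
population and a derived northern-edge population are each acclimated to
cold, control and warm conditions, and the question is whether the derived
population has *lost* plasticity — genetic assimilation — by constitutively
expressing ("frontloading") genes the ancestral population must induce, and
whether miRNAs regulate that divergence.

## What the package computes

**Differential expression.** Gene counts are filtered (< 1 CPM in at least
half the samples), TMM-normalized, and fit per gene with a negative-binomial
GLM, `Var(y) = μ + αμ²`, log link, offsets = log effective library sizes:

```
log μ = β₀ + β_R·Region + β_C·Cold + β_W·Warm + β_RC·Region:Cold + β_RW·Region:Warm
```

with reference cell S_CK. Wald contrasts give the seven pairwise
comparisons (S_Cold vs S_CK, …, N_CK vs S_CK) and the two interaction
contrasts; BH adjustment is applied within each contrast. DEGs require
|log₂FC| > 1 and p_adj < 0.05 (both strict); miRNA DE uses p_adj < 0.05 only.

**Plasticity evolution.** Genes with a significant Region × Acclimation
interaction are classified by their within-region post-hoc responses:
*assimilated* (ancestral response only), *evolved plastic* (derived only),
*accommodated* (both, same direction), *reversed* (both, opposite),
*unclassified* (neither). Category shares are tested with one-proportion
Z-tests against an equal split; frontloaded genes are the intersection of
genes up in N vs S at control with genes cold- (or warm-)induced within the
southern region.

**Co-expression.** Unsigned weighted network `a_ij = |cor(x_i,x_j)|^β`
(β from the scale-free topology criterion), topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
average-linkage clustering of 1 − TOM with static cut, minimum module size
30, eigengene merging at dissimilarity 0.25, module–trait Pearson
correlation (cold-tolerance rule: p < 0.05 and r < −0.5 against CT_min),
gene significance GS and module membership MM, hubs at MM > 0.8 and GS > 0.8.

**miRNA tools.** Dot-bracket parsing; stringent hairpin filters (score > 10,
mature/star 20–26 nt, randfold p < 0.05, ≥ 16 paired arm positions,
loop ≥ 8 nt, exact 2-nt 3′ overhangs on both strands); priority-based
genomic/read-class assignment; small-RNA length and 5′-base summaries.

**Target networks.** Multi-source prediction consensus (all sources by
default), Pearson filter r < −0.4 on log₂ TMM-CPM expression, and coverage
reports against DEG, frontloaded and hub gene sets.

**Synthetic data.** `plastevo.simulate` plants all of the above as ground
truth — reaction-norm classes as log₂ shifts of NB cell means, trait-coupled
co-expression modules, miRNA–target couplings, and hairpins that pass or
fail exactly one structural criterion — so every stage is testable without
external data.

## Worked example

`python examples/01_plasticity_pipeline.py` simulates 2,000 genes across the
six design cells (6 replicates each, planted |log₂FC| = 3), runs the full
pipeline and prints:

```
2000 genes x 36 samples after filtering

673 genes with a significant Region x Cold interaction:
category
assimilated        298
accommodated       131
evolved_plastic    123
reversed           118
unclassified         3

agreement with planted classes: 95.3%

Category enrichment against an equal 25% share (Z-test):
                   k    n  proportion    p0       z      p
assimilated      298  670       0.445  0.25  11.643  0.000
...
frontloading: 185 genes elevated in N at control; 100.0% of them
cold-induced in S (frontloaded), 0.0% still induced in N
```

The classifier recovers 95% of the planted classes; the assimilated excess
(z = 11.6) reflects that frontloaded genes are planted with an assimilated
reaction norm, and the frontloading report shows the planted pattern —
derived-population baseline elevation with ancestral-only induction.
`examples/02–04` walk through module detection, hairpin filtering and the
target network the same way.

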