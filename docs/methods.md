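# Methods

This note documents the models, numerical choices and known limitations of
`plastevo`. It is the package's own account of its procedures; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Differential expression engine

Counts are modeled per gene as negative binomial with the NB2
parameterization, `Var(y) = μ + αμ²` (α ≥ 0), log link, and a fixed-effects
design `~ Region + Acclimation + Region:Acclimation` with reference cell
S_CK; offsets are log effective library sizes (raw library size × TMM
factor). The engine is deliberately self-contained rather than a wrapper
around an external DE package: the downstream reaction-norm classification
consumes raw p-values and unshrunk log₂ fold changes from nine related
contrasts, and owning the engine keeps its behavior fixed and testable. It
is validated against `statsmodels` GLM fits (NegativeBinomial family) on
random instances and against closed forms in saturated cases.

*Dispersion.* Per gene, a pooled method-of-moments estimate: within each
design cell with ≥ 2 replicates, counts are scaled to geometric-mean depth,
and `α̂_cell = (s² − μ̄·h) / μ̄²` where `h` is the mean reciprocal depth in
the cell (the depth-corrected Poisson expectation); cells are pooled with
df weights. The raw estimate is then averaged half-and-half with a
running-median mean–dispersion trend (window ≈ n_genes/20, minimum 11) and
capped to [1e−8, 10]. The equal-weight shrinkage is a simple stabilizer;
under an all-null simulation (2,000 genes, 6 replicates/cell) it yields raw
interaction p-values that pass Kolmogorov–Smirnov uniformity and a 5%-level
type-I rate of ~0.05–0.06, which is the calibration the pipeline needs.

*Fitting.* Fisher-scoring IRLS vectorized across genes (weights
`μ/(1+αμ)`), convergence at relative deviance change < 1e−8 or 100
iterations, linear predictor clipped to ±30 to keep degenerate genes
finite, and a 1e−10 ridge on the normal equations so all-zero genes solve
without special-casing. Coefficient covariance is the inverse expected
information; Wald contrasts use two-sided normal p-values and BH adjustment
within each contrast (the conventional reading when a study reports
per-comparison FDR).

*Thresholds.* DEG calls use strictly `|log₂FC| > 1` and `p_adj < 0.05`;
boundary values are excluded. miRNA DE omits the fold-change gate, since
significance alone defines miRNA DE in this design.

## Reaction-norm classification

Only interaction-significant genes (BH-adjusted interaction p < 0.05 on the
relevant acclimation arm) are classified. Post-hoc within-region responses
use the raw Wald p at 0.05 — the post-hoc test is conditional on a
significant interaction, and a flag switches to adjusted p for users who
prefer it. Accommodated requires both responses significant with the same
sign; the significant interaction itself certifies that their magnitudes
differ, so no additional magnitude test is imposed. The category Z-test
compares each category's share among classified genes to p₀ = 0.25 (equal
share across the four named categories, unclassified excluded), two-sided,
no continuity correction; p₀ is exposed as an argument.

Frontloading is a set intersection built from full DEG calls
(|log₂FC| > 1, p_adj < 0.05): B = up in N vs S at control, I_S / I_N = up
under the acclimation arm within each region. Frontloaded genes are B ∩ I_S;
the share of B in I_N is reported as a check that the derived population's
elevation is constitutive rather than inducible.

## Co-expression workflow

Unsigned adjacency `|cor|^β` on log₂ TMM-CPM expression. The soft threshold
is the smallest power whose signed scale-free fit R² (log₁₀ frequency vs
log₁₀ connectivity over 10 equal-width bins, sign taken from the slope)
reaches 0.8, falling back to the best-fitting power — small synthetic
datasets often peak below 0.8, and the fallback keeps the workflow running
rather than failing. TOM uses the standard unsigned formula; symmetry,
unit diagonal and the [0, 1] range are asserted on every call.

Modules come from average-linkage clustering of 1 − TOM with a **static cut
at height 0.95**. The dissimilarity between unrelated genes concentrates at
~0.98–1.0 while within-module values sit around 0.5–0.7, so 0.95 cleanly
separates real modules from the noise ceiling; a cut at 0.99 absorbs
unstructured genes into modules and can fuse distinct blocks. The full
dynamic tree cut algorithm is not reimplemented; the reported parameters it
shares (minimum module size 30, eigengene-merge threshold 0.25) are
honored, and module recovery is validated against planted truth instead of
against any particular reference clustering. Eigengenes are the first
principal component of the module's row-standardized expression,
sign-anchored to correlate positively with the module's mean standardized
profile so module–trait correlation signs are reproducible.

Module–trait statistics are Pearson correlations with t-distributed
p-values (df = n − 2). The cold-tolerance rule flags modules with p < 0.05
and r < −0.5 against CT_min (lower CT_min = better cold tolerance, hence
the negative sign); the symmetric heat rule uses r > +0.5 against CT_max.
Hub genes require strictly MM > 0.8 and GS > 0.8; exported hub networks
keep edges with TOM > 0.08.

## miRNA hairpin filters

All seven criteria are evaluated from the precursor sequence, its
dot-bracket structure and the mature/star spans (0-based, half-open):
score > 10 (strict), arm lengths 20–26 nt inclusive, randfold p < 0.05, arm
complementarity counted as mature positions whose structure partner lies in
the star span (≥ 16), loop measured as the sequence distance between the
inner ends of the two spans (internal pairing does not reduce it), and 3′
overhangs measured from each arm's last position paired into the partner
arm to its span end. The overhang rule defaults to exactly 2 nt — the
canonical Drosha/Dicer product — with a `min` mode accepting ≥ 2 for
laxer pipelines. The verdict is the conjunction of the seven flags, asserted
as such.

Priority assignment (genomic position 5′UTR > 3′UTR > exon > intron >
intergenic; read class known miRNA > ncRNA > repeat > exon > intron >
unknown) is backed by an `intervaltree` index and verified against an
all-pairs brute-force scan.

## Target network

Consensus requires a pair in all prediction sources by default. The
built-in seed matcher (canonical 6mer/7mer-m8/7mer-A1/8mer sites
complementary to miRNA positions 2–8) is a stand-in source for end-to-end
testing; external predictor tables are ingested as (miRNA, gene, source)
TSVs. The correlation filter keeps pairs with Pearson r strictly below
−0.4 computed on log₂ TMM-CPM values across matched samples (the scale is a
package choice; correlations on raw counts would be confounded by shared
library depth). Zero-variance series drop the pair with a recorded reason.

## Synthetic-data generator

The generator emulates the study design: 2 regions × 3 acclimation
temperatures, 6 replicates per cell by default (two pooled populations of
three replicates each), NB counts with log-normal baselines
(log₂ mean 7.5, sd 1.0 → ~180 counts typical), gene-wise dispersions
log-normal around 0.05, library-depth factors log-normal(0, 0.3²) so TMM
has composition to correct, and planted |log₂FC| = 3 on the cold arm.
Reaction-norm classes are additive shifts of cell means: assimilated genes
shift S_Cold and elevate every northern cell (the induced state made
constitutive); accommodated genes give the derived region one third of the
ancestral response; evolved-plastic genes shift N_Cold only; reversed genes
shift the two regions oppositely. Frontloaded genes are assimilated-type
with the direction forced upward (frontloading is directional by
definition); their expected reaction-norm category is therefore
assimilated, and frontloading recovery is scored by the set-intersection
detector instead.

Modules are planted on null genes as shared latent factors with loadings
uniform on [0.5, 1.2] and amplitude 1.5 log₂ units; the first module's
latent is the standardized cold indicator plus noise, and the simulated
CT_min is 6 °C − 1.5 × that latent + Gaussian noise (sd 0.5 °C, a free
parameter since no per-group phenotype variance is available to calibrate
it), so the cold module correlates negatively with CT_min by construction.
Because planted modules are a large fraction of a small simulated
transcriptome, module analyses normalize on a fuller simulated matrix
(e.g., 1,200 genes) and then build the network on the 200-gene universe of
interest — exactly how real pipelines normalize genome-wide and subset for
network analysis; normalizing a 200-gene universe containing 100 co-moving
genes inverts compositions and is not a scenario the workflow targets.

miRNA coupling gives each regulator miRNA a unit-variance log₂ latent
profile and subtracts it (strength 1.0) from its targets' log₂ means before
redrawing their counts, yielding sample-level correlations well below −0.4
at 16 samples. Synthetic prediction tables put every true edge in all three
sources and make false positives mostly source-specific (two partial decoys
per true edge and source, all-source decoys at 20% of the true edge count)
— the premise that makes all-source consensus an effective filter.

Hairpins are assembled from an explicit structural layout (lead, paired
block, 3′ overhang, loop, star pad, reverse-complement paired block,
overhang), so dot-brackets are balanced and index-consistent by
construction; failing cases violate exactly one criterion, and passing
cases include every boundary (mature 20 nt, loop 8 nt, 16 paired positions,
score 10.01).

What the generator does **not** emulate: read-level artifacts (sequencing
error, mapping ambiguity, PCR duplication), gene length effects,
correlated dispersion–mean structure beyond the fitted trend, batch
effects, tissue differences, and genuine biological pathway structure.
Passing tests therefore demonstrate that the statistical machinery recovers
its own planted signal at realistic sizes and noise levels — not that any
particular biological dataset will show these effects.

## Determinism and reproducibility

All generators take explicit integer seeds and use `numpy.random.Generator`;
identical configuration and seed give bitwise-identical outputs (asserted
in tests). `scripts/acceptance.py` derives every sub-seed from its `--seed`
argument. Simulation sizes used there (2,000 genes × 36 samples for
calibration and recovery, 20 replicate simulations for the network stage)
were chosen to make the reported rates stable to within a few tenths of a
percent across seeds while completing in seconds.

## Known limitations

- The DE engine is a documented stand-in, not a re-implementation of any
  published package; exact numerical agreement with DESeq2/edgeR output is
  a non-goal (no LFC shrinkage, no outlier replacement, no independent
  filtering).
- The static tree cut has no deep-split control; very close or nested
  modules that dynamic tree cut would separate may merge.
- The Z-test null share p₀ = 0.25 is a declared default for "no category
  enrichment", not an inference from data.
- The seed matcher ignores site context (AU content, position in UTR) and
  free-energy scoring; it is a consensus stand-in, not a predictor.
- Whether low-expression filtering is applied jointly across tissues or
  per tissue is exposed by simply passing the sample subset of interest;
  the joint behavior is the default reading.
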