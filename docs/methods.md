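# Methods

## The analysis in one paragraph

The pipeline quantifies, per intestinal epithelial cell type, how much of a
high-fat-diet perturbation of gene expression is reversed by vertical sleeve
gastrectomy.  Two filtered DEG lists are built per cell type with a hurdle
model — diet (HFD sham vs LFD sham) and surgery (HFD VSG vs HFD sham) — and
their intersection is split by direction.  A gene significant in both lists
with opposite signs is *rescued*; Rescue % normalizes the reversed count by
the diet list, Specificity % by the surgery list.  A rescued gene is further
*restored to baseline* when the residual contrast (HFD VSG vs LFD sham)
shows no remaining significant difference at the same thresholds.  All of
this is exercised end-to-end on synthetic droplet data with planted truth.

## Hurdle differential expression

Single-cell expression is zero-inflated, so the test has two parts sharing
one design (intercept, group indicator, covariates):

* discrete — logistic regression of detection `1{y > 0}`;
* continuous — ordinary least squares of `y | y > 0` with profiled σ².

The statistic is the sum of the two likelihood-ratio statistics for the
group coefficient, compared to χ² with df = number of informative parts.  A
part is dropped (df − 1) when degenerate: all/none detected for the discrete
part; fewer positive cells than parameters + 1, a single represented group,
or zero variance for the continuous part.  Quasi-complete separation in the
logistic part (|η| > 25 at the optimum) falls back to the detection part
alone, since the positive-cell design is then confounded with the group.
The logistic MLE is computed by Newton/IRLS with step-halving; a vectorized
variant solves all genes of a contrast simultaneously (genes share the
design matrix; only the response differs), which is what makes whole-bundle
DE take seconds rather than minutes.  Correctness is pinned by a test
comparing the statistic with an independent BFGS maximization of the same
likelihoods to 1e-6 on ≤ 30-cell fixtures, and by a type-I calibration test
(2000 null NB genes, 200 cells/group, empirical rate required in
[0.02, 0.08] at nominal 0.05).

log2FC is the difference of mean log2-normalized expression *including
zeros* (the convention of cluster-marker tooling), not the model
coefficient; direction and the |log2FC| > 0.50 gate use this quantity.
"Greater than" is read strictly for all three DEG gates (p < 0.05,
padj < 0.20, |log2FC| > 0.50), and BH adjustment is applied within each
(cell type, contrast) family over the genes actually tested (detected in
≥ 10 % of either group).  Covariates are z-scored within the tested cell
set: detected-gene count always, mitochondrial read fraction in the
`ngenes_plus_mito` mode used for the mitochondrial-panel robustness rerun.

## Soup (ambient RNA) model

`inject_ambient` replaces a Binomial(tᵢ, ρ) portion of each cell's counts
with multinomial draws from the dataset-wide, library-size-weighted mean
profile, preserving totals exactly, and appends ambient-only empty droplets
(totals 20–90).  Estimation inverts this: the soup profile is the summed
counts of barcodes with ≤ 100 total counts; cells are coarsely clustered
(PCA + KMeans, k = 8, fixed seed) jointly across samples; a gene is
"expressed" in a cluster when its pseudobulk share is ≥ 1/5 of the top
cluster's share, and genes expressed in at most half the clusters are
markers.  Whatever a cluster shows of markers it does not express must be
soup, so ρ per sample is the pooled ratio of observed off-cluster marker
counts to their soup expectation (sample total × soup fraction), clipped to
[0, 0.5].  Pooling counts rather than averaging per-gene ratios avoids the
downward bias of minimum order statistics; joint clustering is essential
because a sample containing a single cell type cannot support its own
cluster structure (per-sample clustering produced a ρ̂ of 0.33 against a
truth of 0.05 in one seed, and a flood of spurious DEGs downstream).
Correction subtracts `ρ̂ · tᵢ · profile_g` from each nonzero count with
round-half-away-from-zero, clipped to [0, count] — it never increases a
count and keeps the matrix integral.  Measured recovery: mean |ρ̂ − ρ| ≈
0.002 at ρ ∈ {0.03, 0.165, 0.279} on clean bundles; with 5 % doublets in
the mix ρ̂ runs ~0.02 high (heterotypic doublets mimic contamination), which
is shared across samples and harmless to the contrasts.

## Doublets

Synthetic truth: `round(rate · n)` appended barcodes, each the exact sum of
two distinct same-sample cells with totals above the empty threshold.
Detection embeds real plus artificial pair-sums in 20-PC space of
log-normalized counts and scores each barcode by the fraction of artificial
neighbors among its 20 nearest; calls take the top `expected_rate` quantile.
Homotypic doublets (same cluster twice) are largely invisible to this score
— as they are to production doublet callers — and land inside their
cluster, where they are harmless; the planted-vs-singlet score separation is
asserted by a one-sided Mann–Whitney test at rate 0.05, n ≈ 1000.

## Cell filters

`keep ⇔ (genes detected ≥ 750) ∧ (mito fraction ≤ 0.20) ∧ (not doublet)`.
The boundary semantics are literal: exactly 750 genes and exactly 20.00 %
mito are kept, because the stated removal criteria are "< 750" and "> 20 %".
Filtering is idempotent and refuses QC tables that do not cover every
barcode.

## Clustering, integration and annotation

Normalization is `log2(1 + 10⁴ · c / total)`; HVGs are the top-2000 genes
by binned standardized dispersion (variance/mean z-scored within 20
mean-expression bins — implemented directly so constant genes have a
defined dispersion of 0 and selection is exactly deterministic), excluding
mitochondrial genes, whose 13-gene block otherwise dominates the dispersion
ranking.  The scaled HVG matrix is adjusted before PCA: per-cell covariates
(detected genes, mito fraction) are regressed out gene-wise, and gene means
are centered within each sample ("integration-lite").  The centering stands
in for anchor-based sample integration: without it, the planted
condition-wide shifts at study conditions split clusters by condition at
resolution 0.4, which is precisely what integration prevents on real data.
Clustering is Leiden (igraph flavor, 2 iterations, fixed seed) on a 15-NN
graph over 30 PCs at resolution 0.4.

Cluster markers come from a one-vs-rest hurdle test restricted to genes
already clearing the log2FC ≥ 0.5 and 10 %-detection gates (the gates
commute with ranking, and cut the tested set ~20-fold); the top 100 by p
are compared with reference lineage marker sets, score = |top ∩ ref|/|ref|,
argmax above a 10 % floor, ties broken by mean marker expression.  The
reference ships with the package (stem, enterocyte, Paneth, goblet, tuft,
EEC, and the Gzma/Gzmb/Itgae/Ccl5/Cd7/Cd69/Cd3g/Cd8a immune signature);
clusters whose best match is the immune set are dropped before DE.  The
alternative overlap denominator (the enriched list) was considered and
rejected: with a fixed top-100 list it penalizes small reference sets.

Downstream contrasts run per *annotated cell type*, merging Leiden
subclusters that share a label.  This is the cluster unit the reversal
analysis needs: a subcluster carrying only one condition cannot support a
contrast, while the cell-type group always spans all three arms.

Cell-cycle scores are bin-matched control differences (25 mean-expression
bins, 50 seeded control genes per marker, canonical symbol ordering so the
result is invariant to gene storage order); phase = argmax(S, G2M) if
either is positive, else G1.

## The synthetic generator

Defaults are the study conditions used throughout the tests: 3 epithelial
cell types (stem/crypt, enterocyte/villus, Paneth/crypt), 300 cells per
cluster per condition, 1500 genes, NB dispersion 0.1, log-normal gene means
(σ = 1) scaled so the median cell has ~3000 counts and ~860 detected genes
— putting the 750-gene filter inside the real distribution, ~11 % of cells
below it.  Cluster identity is carried by 40 near-exclusive markers per
type (on: ×2³; off: ×0.005 — intestinal lineage markers such as Lyz1 or
Lgr5 genuinely are near-exclusive, and the off-state is what makes soup
estimation identifiable).  Diet effects hit 10 % of genes at ±1.5 log2 in
both HFD arms; 60 % of them revert fully to the control mean under VSG
(partial reversion is a config option, `rescue_completeness`); 5 % of genes
are surgery-only effects.  Mitochondrial reads are generated by drawing a
per-cell mito fraction from Beta(2, 23) (mean 8 %, ~3 % of cells past the
20 % gate) and distributing the implied mito total over a weighted 13-gene
panel; six panel genes are down ×1.5 log2 under HFD and restored under VSG,
emulating the electron-transport-chain rescue the analysis is designed to
detect.  Stem cells get a ×2 boost on the S/G2M gene sets.  One pooled
sample per condition × compartment is generated (no biological replicates),
matching the pooled design the pipeline targets.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: batch chemistry and replicate-level variance,
continuous differentiation gradients within cell types, UMI collisions,
gene–gene correlation beyond cluster/condition structure, and partial
(rather than all-or-none per gene) rescue by default.

## Numerical and determinism choices

All randomness flows from explicit seeds (`numpy.random.default_rng`);
stage seeds derive from the config seed via `SeedSequence`.  PCA uses
ARPACK, KMeans a fixed `random_state`, Leiden a fixed seed, so a rerun of
the pipeline with the same config is byte-identical across every TSV (this
is itself a test).  Soup correction rounds half away from zero;
`adjust_bh` delegates to the standard step-up implementation and is checked
against brute-force enumeration; hypergeometric p-values are upper tails
(`P[X ≥ k]`) checked against exhaustive counting for N ≤ 25.  Undefined
rescue ratios (zero denominators) are NaN-flagged, never coerced to 0.
Degenerate inputs are first-class: empty bundles round-trip, all-zero genes
are untested, clusters missing a contrast arm are skipped with a log line,
and the pipeline aborts with "no cells after QC" rather than continuing on
an empty matrix.

## Problem sizes

Tests run the generator at 100–300 cells per cluster per condition and
500–1500 genes.  The acceptance script uses 6 pipeline seeds for rescue
recovery (plus 2 per level for the specificity monotonicity check over
surgery-only fractions {0, 0.05, 0.15}), 10 seeds per ρ level, 10 seeds for
clustering recovery, and 2000 null genes for calibration; the pytest suite
runs the larger 10/20-seed versions of the same checks.

## Known limitations

* Specificity pooled over compartments reports directional percentages
  against pooled totals (directional denominators are not carried through
  per-cluster rows).
* The enrichment stage reports plain hypergeometric + BH; composite scores
  that mix p-values with rank z-scores are intentionally not replicated.
* Real-data mode (CellRanger triplets) shares every code path but is not
  covered by ground-truth tests, only by format round-trips.
* With only one pooled sample per group, the contrasts treat cells as
  replicates, as the upstream tooling does; inference is conditional on
  that design and inherits its pseudoreplication caveats.
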