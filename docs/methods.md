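# Methods

This note documents the statistical procedures implemented in `ibrd`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Differential expression and persistent genes

Counts are normalized by median-of-ratios size factors: for genes with
strictly positive counts in every sample, factor_s = median_g
(count_gs / geometric-mean_g). The working expression matrix is
log2(normalized count + 1), with normalized counts expressed per million of
the geometric-mean effective library. This makes the matrix exactly
invariant to rescaling all columns by a common constant — a fixed
pseudocount on a depth-dependent scale would not be — at the cost of a
cohort-level reference library; projection of external cohorts therefore
assumes comparably normalized input, the same assumption a
variance-stabilizing transform carries.

The differential test is an ordinary linear model per gene with the group
contrast plus categorical covariates (batch, location, optionally age bin
and gender), a two-sided t-test on the contrast coefficient and
Benjamini-Hochberg adjustment. This is a deliberate, documented stand-in
for a negative-binomial engine: it is exactly calibrated under the null on
log-scale data (verified by simulation in the test suite), vectorizes to a
single least-squares solve for all genes, and any externally computed DE
table with (log2fc, p, padj) columns can be substituted — selection and
persistence logic are engine-agnostic. Genes with total count below 5 are
removed before testing ("total across samples" is the chosen reading of the
count filter; it is a function argument). DEG bounds are inclusive on
|log2FC| ≥ 2 and strict on padj < 0.05. Persistent genes are the
intersection of same-direction DEG sets from the active-vs-control and
EH-vs-control contrasts.

## Cluster frequencies and their tests

Relative frequencies are cells-per-cluster over cells-per-biopsy; rows sum
to one exactly. Group differences use Kruskal-Wallis (average ranks, tie
correction) followed by Dunn's pairwise mean-rank comparisons; BH is
applied within each cluster's pairwise family (per-panel correction; a
global family is a one-line change). Reported percentages are rounded
half-away-from-zero to two decimals only at the reporting boundary.

## TCR clonotypes

A clonotype is the exact (alpha CDR3, beta CDR3) nucleotide pair. Cells
missing either chain are dropped; among multiple contigs of one chain the
highest-UMI contig wins, ties broken by lexicographically smallest sequence
so calling is deterministic. Non-productive contigs are excluded by default
(flag to include). Expansion classes count cells and unique clonotypes with
clone size strictly above 1, 5, 10, 20; "expanded" elsewhere means size
≥ 2. Sharing counts deduplicate each clonotype to one per group before
computing Venn-region sizes.

## Bipartite correlation network

Spearman coefficients (average ranks; two-sided p via the t approximation)
between every gene and every cluster over the matched-biopsy intersection;
within-modality correlations are never computed. Constant features yield
undefined entries that are excluded from the BH family rather than imputed.
In FDR mode the BH family is all gene x cluster pairs jointly and entries
with padj strictly greater than alpha are zeroed; nominal mode zeroes on
raw p ≥ alpha and still reports padj. Signature selection keeps features
with at least `min_degree` surviving edges, ordered by degree then maximal
|rho|.

## IBrD score

PCA is computed on centered, unit-variance signature genes (zero-variance
genes dropped with a warning); k is the smallest component count reaching
80% cumulative explained variance. The trajectory is a single-lineage
principal curve via the Hastie-Stuetzle iteration: initialize with the
first-component line; then alternate orthogonal projection onto the current
polyline, coordinate-wise lowess smoothing (local linear, fixed span,
no robustness iterations) against arc length, and reparameterization by
cumulative arc length. An iterate that would increase the total squared
orthogonal distance is rejected, making the objective non-increasing;
convergence is a relative objective change below `tol` (default 1e-3,
max 10 iterations). The span default is 0.6; on a noisy half-circle
benchmark (n = 200, noise SD 0.05) the fitted curve's mean orthogonal error
is ~0.07, within twice the noise SD.

Pseudotimes are oriented so the control group's mean is at the low end
(`orient_low` overrides for cohorts without controls) and min/max-normalized
over the training samples, so training scores span exactly [0, 1].
Projection of new samples standardizes by the stored means/SDs (never
re-estimated), rotates by the stored matrix, truncates to k components and
projects orthogonally onto the stored polyline — distance ties resolve to
the smaller arc length. Projected scores are not clamped; values outside
[0, 1] carry an `out_of_range` flag. The model serializes losslessly to
JSON; save → load → project is bit-identical.

## Random-signature null and mixed models

The null draws gene sets without replacement from the pool of all regulated
genes (union of up and down DEGs of both contrasts), fits a scaled PCA per
draw and records each disease group's centroid distance to the control
centroid on PC1-PC2 plus the explained variances. Draws are sized to the
observed signature: scaled-PCA score magnitudes grow with gene-set size, so
equally sized draws are the fair comparison (the original design drew 81
genes against an 81-gene signature). The one-sample Wilcoxon against the
observed distance uses the exact signed-rank distribution for n ≤ 25
without ties, otherwise the continuity-corrected normal approximation;
zero differences are dropped with a warning; two-sided by default.

Per-PC validation fits `PC ~ activity + anti_tnf + location + (1|patient)`
by REML (statsmodels MixedLM); p-values are Wald tests from the REML fit
(normal reference — the residual-degrees-of-freedom approximation), with
Bonferroni correction over the number of PCs tested, capped at 1. A CD-vs-UC
variant swaps disease status for IBD phenotype on the controls-excluded
subset.

## 16S statistics

A zOTU is removed iff its relative abundance is below 0.25% in **every**
sample AND its prevalence is ≤ 10% (the conjunctive reading; a disjunctive
switch exists). CLR replaces zeros by half the sample's smallest nonzero
proportion with renormalization — chosen because it preserves exact
per-sample scale invariance — and per-sample CLR values sum to zero.
Richness counts nonzero zOTUs; Shannon-effective is exp of the Shannon
entropy of nonzero proportions, so it is bounded by richness with equality
iff uniform. Differential abundance is a two-sided rank-sum test on
relative abundances (CLR mode available) per taxon and group pair, BH over
the full taxon x pair family. Time-series summaries average relative
abundance across a patient's locations per phase; patients missing a phase
are excluded with a warning.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at a
desk scale chosen to run in seconds: 12 IBD patients x 2 sites x 2
timepoints (baseline active → follow-up EH) plus 5 controls = 58 biopsies;
2000 genes with 60 persistent-up and 60 transient-up genes at log2FC 3;
NB dispersion 0.1; log-uniform library sizes (1e5–4e5); 12 T-cell clusters
with a rare Th17-like cluster (Dirichlet concentration 0.4 vs. 5.0
elsewhere); 300 zOTUs at fixed depth 1e4.

A latent per-biopsy gradient g encodes residual-disease depth: controls 0,
EH ~ U(0.2, 0.6), active ~ U(0.6, 1.0). The Th17-like cluster's Dirichlet
concentration is inflated by `gradient_coupling * g` (default 10). Half of
the persistent genes are additionally modulated as
log2-shift = lfc_persistent * (0.75 + 0.5 g): a single scalar cannot act as
both a concentration increment and a log2FC modulation, so gene-side
coupling is this fixed documented form, chosen to keep the group-mean
|log2FC| above the DEG threshold in EH while making expression monotone in
g within groups. Clone sizes are drawn from a Zipf law (exponent 2.5,
truncated at 200) per patient, so most clonotypes are singletons with a
heavy expanded tail, and clones persist across a patient's biopsies. Half
of each IBD patient's ablated zOTU set is a cohort-shared core
(consistently depleted taxa), half patient-specific dysbiosis.

Gene identities and baseline means are keyed to the configuration seed
while sampling noise follows the call seed, so independent batches from the
same configuration share which genes are disease genes — the property that
makes out-of-sample projection meaningful.

What the generator does **not** emulate: batch effects beyond a scalar
offset, gene-gene correlation beyond the shared gradient, V/J gene usage or
realistic CDR3 sequence statistics, UMI errors, phylogenetic structure
among zOTUs, and compositional coupling between modalities. Tests passing
on this cohort therefore demonstrate correctness of the computations and
recoverability of planted structure, not performance on real tissue data.

## Problem sizes and determinism

The test and acceptance runs use the default cohort (58 biopsies, 2000
genes) with 10 seeds for recovery/ordering properties, 20 seeds for null
calibrations (smaller gene/cell counts per seed), and 200 draws for the
null model. All randomness flows from named substreams of a single seed
(counter-based SeedSequence keys), so modality generation order never
changes results and identical configurations are byte-identical.

## Known limitations

- The DE stand-in loses power relative to a dispersion-shrinking NB model
  at very low counts; the import path exists for that reason.
- Mixed-model p-values use the normal reference; with few patients they are
  mildly anti-conservative (calibration verified at the cohort sizes used).
- The principal curve is single-lineage by design; branching disease
  trajectories would need a different trajectory model.
- CLR zero replacement is a simple substitution; count-model alternatives
  (e.g. Bayesian multiplicative replacement) are out of scope.
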