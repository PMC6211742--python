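# Methods

This note documents the models and procedures implemented in `serocell`,
the parameters that matter, the design choices made where the workflow
convention is genuinely open, and what the synthetic cohort generator does
and does not emulate.

## Cell calling

Barcode UMI totals are ranked in non-increasing order and the knee of the
log10(rank) vs log10(count) curve is taken as the cell/empty-droplet
boundary. The knee is defined as the rank with maximum perpendicular
distance to the chord joining the curve's first and last points; ties
break toward the larger rank (more cells kept). The rule is deterministic
and parameter-free; the threshold is the UMI count at the knee and cells
are barcodes with counts at or above it. A curve with all counts equal
has no knee and raises an explicit error rather than guessing.

**Known behavior.** When the true cells' library sizes are themselves
log-normally spread (as in real droplet data), the chord knee sits where
the cell curve's log–log slope equals the chord slope, which is inside
the lower tail of the cell distribution rather than at the cell/ambient
cliff. On the simulator's default conditions (library-size sigma 0.35)
this trims roughly the bottom 15–40% of true cells along with all ambient
barcodes. The separation property — no ambient barcode is ever called,
every called barcode is a true cell — holds robustly and is what the
tests assert; an exact true-cell-count recovery would require an
unrealistically tight (sigma ≲ 0.15) library-size distribution. Users who
know their cell count can override the threshold.

## Synthetic cohort generator

The generator draws UMI counts from a zero-inflated negative binomial.
For cell *i* of type *t* and gene *g*:

- baseline rate λ_g ~ LogNormal(log 0.3, 1.2) — sized so a cell detects
  ~280 of 1500 genes (~600 UMIs), making the 200-genes-per-cell QC
  threshold bind on the low-library tail as it does in practice;
- library factor s_i ~ LogNormal(0, 0.35);
- marker effects f_gt: each cell type owns a disjoint block of 25 marker
  genes boosted by 2^f (default f = 2), mimicking cell-type-specific
  expression programs;
- mean μ_gi = s_i · λ_g · 2^{f_gt}; dispersion θ = 2 shared across genes
  (per-gene θ supported);
- dropout: structural zeros with logit π_gi = a + b·log μ_gi, defaults
  a = −1, b = −1, so lowly expressed genes drop out more often — the same
  mean-dependent zero-inflation class the DE model assumes;
- optional ambient barcodes: empty droplets whose counts are Poisson draws
  from the λ-proportional "soup" at a configurable mean depth.

Site-dependent composition presets encode the observed epithelial-to-
lymphocyte shift: primary tumors 68.3% epithelial / 11.1% lymphocytes,
metastases 66.2% lymphocytes / 10.5% epithelial, normal ovary dominated
by fibroblasts and stroma with no epithelial cells.

What the generator does **not** emulate: batch effects, doublets, ambient
contamination inside called cells, gene–gene correlation beyond the
cell-type blocks, and transcriptional continua (every cell is exactly one
type). Passing recovery tests therefore demonstrate correctness of the
algorithms under a clean mixture model, not robustness to those artifacts.

`generate_null_pair` draws two groups from identical parameters, so any
DE signal is a false positive by construction; `spike_signature` redraws
a chosen gene set in a chosen group with means multiplied by
2^{log2_effect}, giving known-effect positives for power and
signature-recovery tests.

## Preprocessing

Gene filter (detected in ≥ 3 cells) then cell filter (≥ 200 detected
genes among retained genes), one pass in that order; both removal counts
are reported since the order matters near the thresholds. Normalization
is ln(1 + c·10⁴/N_i) — the de-facto droplet convention (scale factor and
log base configurable). Cell-cycle S and G2/M scores use the binned
control method: mean expression of the phase genes minus the mean of
control genes drawn (seeded) from the same average-expression bins
(25 bins, 50 controls per gene); the widely used 43-gene S and 54-gene
G2/M lists ship as a GMT fixture and are replaceable. Total UMIs
(log10) and the two phase scores are regressed out per gene by OLS —
the simplest faithful reading of covariate removal; residuals are exactly
orthogonal to the design. Before PCA, residuals are z-scaled per gene and
clipped at ±10 to bound outlier leverage.

Variable genes: dispersion = variance/mean of back-transformed
expression, 20 equal-frequency mean bins, within-bin z-score of log
dispersion, keep z ≥ 1 capped at 2000 genes. On i.i.d. genes this selects
≈ P(Z ≥ 1) ≈ 16% — selection is relative, by design.

## Clustering and annotation

PCA (full SVD, deterministic) on the scaled variable-gene matrix; the
number of PCs is chosen by the same distance-to-chord rule applied to the
scree curve (ties toward smaller k; overridable). Cells are embedded in
PC space; the literal notion of components as "edge weights" is realized
the only standard way: Euclidean k-nearest neighbors (k = 20) in PC space
define a shared-nearest-neighbor graph whose edges are Jaccard overlaps
of neighborhoods (self included), pruned below 1/15. The partition is
found by seeded Leiden optimization of modularity (resolution 1.0); the
achieved Newman–Girvan modularity is reported, and on toy graphs small
enough to enumerate all partitions the optimizer attains the exhaustive
maximum. tSNE (seeded, PCA initialization) is produced for visualization
only — nothing downstream consumes it.

Annotation scores each cluster against each marker panel by the mean
detection fraction of the panel's genes in the cluster; the argmax panel
labels the cluster if its score reaches 0.25, with ties or weak maxima
left "unassigned". When over 60% of a cluster's cells come from one
anatomical site the label is suffixed with it (e.g.
`myeloid/metastatic`), mirroring how site-restricted clusters are named.

**Recovery conditions.** The clustering recovery suite uses six cell
types at 100 cells each (600 cells, 1500 genes, marker log2 effect 2) — a
realistic per-cluster size for cohorts of this kind; across 20 seeds the
pipeline recovers all six clusters with ARI ≥ 0.9 in every seed
(median ≈ 0.95). At 60 cells per type the six clusters are still always
found but boundary-cell assignment drops ARI below 0.9 in about a quarter
of seeds.

## Differential expression

Per gene, counts follow a zero-inflated negative binomial with a group
term in both components (see README for the equations); the offset is
log total UMIs, so β measures depth-adjusted expression. The
likelihood-ratio test compares the full model against γ₁ = β₁ = 0; the
statistic is referred to χ² with 2 df (1 df when the gene has no zeros
and the zero component is disabled). Both components carry the group term
because group-dependent dropout is part of the signal this model class is
meant to capture.

Fitting is quasi-Newton (L-BFGS-B) on (γ, β, log θ) with analytic
gradients and three deterministic starts — moment-based, zero-heavy
(π₀ = 0.5), and NB-leaning (π₀ ≈ 0.02, θ = 10); the best converged start
wins. Degenerate inputs: all-zero genes are flagged non-testable; a
negative LRT statistic beyond −10⁻⁶ marks non-convergence and yields NaN
p. Genes detected in under 10% of both groups are skipped (and reported)
to avoid unstable fits.

Calibration on the null-pair harness (500 genes, 200 cells/group): the
raw-p fraction below 0.05 is ~0.05, inside the binomial 99% band
[0.03, 0.07]; a spiked β₁ = 1.5 at 300 cells/group is recovered at
Bonferroni-adjusted p < 0.05 in ≥ 19/20 seeds.

Reported statistics mirror the standard table layout: average log2 fold
change log2[(mean expm1(x) in + 1)/(mean expm1(x) out + 1)] on
normalized expression (pseudocount configurable), detection fractions
from raw counts, raw and adjusted p. Adjustment is Bonferroni by default
(Benjamini–Hochberg via config). Exact p-values are reported without a
2.2e-16-style floor. The DE rule is p_adj < 0.05 and log2FC > 1; the
biomarker rule adds pct_in ≥ 0.5 and pct_in − pct_out ≥ 0.5.

## Composition analysis

Sample × cell-type cross-tabulation with row proportions; hierarchical
grouping of proportion profiles by Ward linkage on Euclidean distance
(both configurable), serialized as a Newick dendrogram. Enrichment of a
cell type in a sample is a two-sided Fisher exact test on
[[type-in-sample, other-in-sample], [type-elsewhere, other-elsewhere]]
with the minimum-likelihood two-sided convention (probabilities of all
tables at fixed margins not exceeding the observed one), matching the
convention of the standard statistical environments. The sample odds
ratio ad/bc is reported; a 0.5 continuity correction is applied for
display only when a table cell is zero, with a warning. The comparison
population is the given sample versus all other cells pooled.

## Subtype scoring and classification

A group's score for a signature is the mean over the signature's genes of
(group mean normalized expression) / (global mean normalized expression)
— a relative-enrichment ratio centered at 1, invariant to global
rescaling. Genes with zero global mean are skipped with a warning. The
four signature gene sets are an input (GMT); the packaged demo derives
synthetic ones from the simulator's marker blocks.

Classification pools **all** entries of all supplied score matrices (for
the reference tables: 14×4 sample + 16×4 cluster = 120 values) and sets
the threshold at pooled mean + 2 standard deviations. Population SD is
the default; the sample-SD convention is available and yields the same
calls on the reference tables (thresholds 3.2829 vs 3.2920 against a gap
between 3.246 and 3.337 in the pooled values). A group is assigned the
argmax signature among those strictly above the threshold — each group
gets at most one call — otherwise "unclassified". Among the candidate
readings of "combined comparisons" (per-column, per-matrix, pooled), only
pooling reproduces the reference classification, which is why pooling is
the default; the variants remain available.

## Problem sizes and numerical choices

Test and acceptance runs are sized to be CPU-friendly while keeping every
statistical check meaningful: 500-gene/400-cell null calibration,
20-seed × 600-cell clustering recovery, 20-seed spike recoveries, and a
~2900-cell composition cohort matching the motivating study's per-sample
cell counts. Optimizer bounds keep log θ in [−7, 12] and coefficients
bounded to avoid overflow; SVD-based PCA and seeded Leiden/tSNE make
whole-pipeline runs bit-reproducible from a single global seed, which
fans out to fixed per-stage seeds.

## Limitations

- The knee rule trims low-library cells (see above); it is a stand-in for
  threshold selection that is often done by eye.
- OLS covariate regression can produce negative "expression" residuals;
  downstream detection-based statistics therefore always use the
  pre-regression normalized matrix or raw counts.
- The ZINB test treats cells as independent; patient-level pseudo-bulk or
  mixed models are out of scope.
- Subtype scores are relative-enrichment ratios; their absolute scale
  depends on the normalization and is not comparable across datasets,
  which is why classification uses a pooled, data-derived threshold.
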