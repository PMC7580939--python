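# Methods

This note records the models, defaults and numerical choices behind
`imhaseq`, and what the synthetic test bed does and does not establish.

## Cell-composition RNA model

Whole-blood RNA is modelled as a mixture over seven cell types.  Each
type contributes (CBC count per μL) × (RNA mass per cell after
hemoglobin depletion).  The per-cell totals are literature values from
human blood cells (rabbit for reticulocytes, converted assuming a 62 fL
mean corpuscular volume); globin depletion removes 70% of RBC RNA and
95% of reticulocyte RNA.  We compute post-depletion masses as the exact
product, giving 0.000171 pg/cell for RBCs and 0.00520 pg/cell for
reticulocytes; the literature figure of 0.00518 for reticulocytes was
evidently carried at higher intermediate precision and is available as
an override (`CellTypeRNAProfile.with_published_depletion`).

Group log2 fold changes in RNA fraction are the difference of group
means of per-dog log2 fractions.  The CI is a Welch two-sample t
interval (robust to unequal group variances); a percentile bootstrap is
available as an alternative.  Dogs with a zero count in a cell type
yield a −inf log2 fraction and are excluded from that cell type's group
statistics.  Note the estimand is the mean of logs, not the log of mean
fractions: with skewed count distributions the two differ (Jensen gap),
and all quoted values use the mean-of-logs convention.

The expression-analysis threshold is the CI bound farthest from zero
across the cell types expected to drive disease biology (reticulocytes,
lymphocytes, neutrophils), rounded up to one decimal.  The pipeline's
DEG filter nevertheless defaults to the round figure 2, which is the
config default `deg_abs_l2fc`.

## Synthetic cohort: what it emulates

The generator is the package's study-conditions definition, not a
tuning knob.  Defaults, chosen once:

* **Cohort**: 18 cases + 18 controls (an analysis cohort after outlier
  exclusion), 2000 genes, library 2 × 10⁶ counts/dog.
* **CBC**: log-normal around group means with CVs 0.35 (neutrophil),
  0.40 (monocyte), 0.35 (lymphocyte), 0.50 (eosinophil), 0.15 (RBC),
  0.30 (platelet), 0.50 (reticulocyte).  Control means are canine
  reference-interval midpoints (RBC 6.5 × 10⁶/μL, reticulocyte 5 × 10⁴,
  platelet 3 × 10⁵, neutrophil 4.8 × 10³, lymphocyte 2 × 10³, monocyte
  4 × 10², eosinophil 3 × 10²).  Case/control mean ratios mirror IMHA
  hematology: neutrophils ×2.5, reticulocytes ×6, RBC ×0.45, monocytes
  ×2, platelets ×0.7; lymphocytes and eosinophils unchanged.  The
  distributional family (log-normal) is our choice: cell counts are
  positive and right-skewed.
* **Expression**: expected count of gene g in dog d is proportional to
  library × Σ_c fraction_RNA(c,d) × signature(g,c), where the signature
  (gene × cell type, columns normalized to sum 1 so that a unit of RNA
  fraction maps to a unit of expected library share) makes ~30% of genes
  exclusive to one cell type and mixes the rest with Dirichlet weights
  over a log-normal per-gene abundance.  Counts are negative binomial
  with variance μ + αμ², α = 0.05 (typical within-group biological
  dispersion for bulk RNA-seq).  Because signature columns are
  normalized, a gene expressed in exactly one cell type has expected
  log2FC equal to that cell type's RNA-fraction log2FC — the link the
  threshold argument relies on.
* **Planted effects**: 50 DEGs at |log2FC| ∈ {2, 3, 4} (balanced signs)
  on broadly expressed genes; two 150-gene modules driven by latent
  factors correlated (ρ = 0.9) with log neutrophil and log reticulocyte
  count, multiplier 2^(2·z).  The amplitude of 2 log2 units per latent
  SD was set so that pathway-program variation dominates per-gene NB
  noise; weaker programs (≤ 1.5) are statistically inseparable from the
  global composition axis under average-linkage detection with a static
  cut, which is itself an informative property of the method.  Planted
  DEG and module gene sets are disjoint.
* **Taxa**: 50 taxa, NB background mean 100 with dispersion 0.5 and
  log-normal library-depth variation (σ = 0.3); two planted taxa with
  case effects of 2 and 3 log2 units.  At these noise levels the 4-fold
  taxon's selection frequency straddles the 0.6 stability cutoff
  (recovered in ~70% of cohorts), while the 8-fold taxon is recovered
  essentially always — recovery claims are therefore made for effects
  ≥ 3 log2 units.
* **qPCR**: triplicate Ct values, Ct = baseline − log2(expression) +
  N(0, 0.15²), with a per-dog input offset (SD 0.3 cycles) common to all
  genes; targets at true folds 0.25 and 0.5, three housekeeping genes at
  fold 1.

What passing tests on this bed do **not** show: the generator has no
sequencing-error or mapping structure, no gene–gene correlation beyond
the planted modules and composition, a single shared dispersion, and
cell-type signatures that are synthetic rather than measured — so
recovery rates here bound what the methods can do under their own
assumptions, not their performance on real blood.

## Differential expression

The test is a deliberately simple NB Wald test: median-of-ratios size
factors (rescaled to geometric mean 1), per-gene method-of-moments
dispersion pooled across the two groups and clipped at zero, log2FC on
group means of normalized counts with pseudo-count c = 0.5/median size
factor, and a delta-method SE.  There is no dispersion shrinkage,
independent filtering, or outlier reweighting; correctness is assessed
by null calibration (type-I error near 0.05, near-uniform p-values) and
planted-effect recovery, not by numerical identity with any particular
tool.  The VST stand-in is log2(count/size factor + 1).  PCA outlier
screening flags samples beyond 4 robust SDs (1.4826 × MAD) of the
centroid distance in the leading three components; the rule is a
documented default since visual inspection has no numeric criterion.

## Enrichment

Pre-ranked scoring uses the weighted KS running sum (hit increments
|score|^w normalized over hits, w = 1; miss decrements 1/(N − hits)).
Ranking ties break by gene identifier.  The null is gene-label
permutation at matched set size; p-values are two-one-sided with the +1
correction (so p ≥ 1/(n_perm+1)); NES divides by the mean |null ES| of
matching sign; FDR is BH across sets — simpler and more conservative
than split-sign pooled FDR, matching the "BH-corrected p ≤ 0.1" rule.
When the running sum's positive and negative extrema tie in magnitude
the positive one is reported.  ssGSEA ranks genes within each sample
(top gene gets rank N), weights member positions by rank^0.25, and sums
the member/non-member ECDF difference.  Pathway-similarity edges use the
mean of Jaccard and overlap coefficients at cutoff 0.375, with a
single-pass filter to nodes having ≥ 2 neighbors.

## Network modules

Unsigned adjacency |r|^β (Pearson), with β the smallest power whose
scale-free fit — the signed R² of log10 frequency vs log10 mean
connectivity over 10 equal-width connectivity bins — reaches 0.8
(fallback: best fit among candidates 1..20).  TOM as standard:
(l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij).  Module detection is
average-linkage clustering of 1 − TOM with a static cut at height 0.99
(a fully specified substitute for dynamic tree cutting); clusters under
30 genes are left unassigned (module 0).  Eigengenes are first singular
vectors of per-gene z-scored module submatrices, sign-aligned to the
member genes.

Merging: the merge parameter 0.30 is interpreted as an eigengene
**dissimilarity** cut height (merge while 1 − r < 0.30, i.e. r > 0.70),
the semantics of the standard eigengene-merge parameter.  Read literally
as "merge while r > 0.30" the rule collapses every trait-linked module
in a case/control cohort, because group structure alone correlates all
responsive eigengenes well above 0.30 — and it would contradict the
coexistence of well-correlated modules in published module-adjacency
matrices.  The literal reading remains available
(`merge_modules(..., merge_on="correlation")`).

Module–trait statistics are Pearson correlations of eigengenes against
raw CBC counts with t-distribution p-values (n − 2 df); GS and MM as
gene–trait and gene–eigengene correlations; selection at GS p ≤ 0.05,
MM p ≤ 0.05, MM ≥ 0.  Overrepresentation is a one-sided hypergeometric
upper tail with BH across sets (replacing any external web service), and
group comparisons use one-way ANOVA with Tukey HSD at p ≤ 0.05.

## Case clustering

Euclidean distances on the full case VST matrix (no feature reduction),
Ward's revised criterion — the squared-distance Lance–Williams update
with heights on the original distance scale, i.e. Ward applied to the
observations themselves.  The SSE curve is computed for k = 1..8 and the
automatic k maximizes the drop ratio SSE(k−1)/SSE(k), a mechanical elbow
rule; the CLI prints the curve and accepts an override since elbow
choices are ultimately judgment calls.  Cluster-difference testing is a
per-gene Welch t with BH correction; on VST (log2) input the group mean
difference is the log2FC and carries a Welch 95% interval.

## Stability selection

Predictors are log2(CPM + 1) taxa abundances, standardized within each
subsample.  B = 100 runs as 50 complementary half-sample pairs.  Per-run
sparsity q = floor(sqrt(PFER·(2π−1)·p)) from the standard per-family
error bound; with π = 0.6, PFER = 2, p = 50 this gives q = 4.  Each run
walks a 50-point geometric penalty path downward from the all-zero end
and takes the first q variables to enter.  The L1-penalized logistic
fits go through liblinear (intercept effectively unpenalized via
intercept scaling, fixed solver seed), which matches a bound-constrained
convex-solver oracle to ~1e-6.  A sensitivity sweep over
π ∈ {0.6, 0.75} and PFER ∈ [1, 2] is built in.

## qPCR

ΔΔCT with amplification efficiency fixed at 2 (doubling per cycle) and
no efficiency correction.  Per dog, ΔCT = mean Ct(target) − mean
Ct(housekeeping) over replicates; the case/control ΔΔCT carries a Welch
95% interval.  Replicates with SD > 0.5 cycles are flagged, never
dropped.  With several housekeeping genes the point estimate is the mean
of per-reference log2FCs and the pooled CI is a Welch interval on the
stacked per-(dog, reference) ΔCT values, so reference-gene disagreement
widens it.

## Degenerate inputs and tie-breaks

Zero-count cell types: excluded from log statistics (composition) or
produce fraction 0.  All-zero genes: log2FC 0, p = 1.  Genes with zero
variance: removed before network construction.  Constant traits: NaN
correlations, propagated.  Gene sets not intersecting the ranked list
are skipped with a warning; sets covering the whole list score the
degenerate maximum and are flagged.  All randomness flows from explicit
seeds; two runs with the same config and seed produce identical tables.

## Problem sizes

Default analyses and the acceptance script run at 2000 genes, 36 dogs,
50 taxa, 200 gene sets × 1000 permutations, 500 replicate cohorts for CI
coverage, and 100 subsample fits per stability selection — sizes at
which every planted effect is comfortably identifiable yet the whole
suite runs on a laptop in about a minute.
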