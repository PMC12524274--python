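# Methods

`klfatlas` re-implements, as a tested pipeline on synthetic data, a
single-nucleus RNA-seq analysis of the Krüppel-like factor (KLF)
transcription-factor family in bovine *longissimus dorsi* muscle from two
breeds (Angus, a beef breed, "ANG"; Holstein, a dairy breed, "HST"). The raw
study data are not publicly deposited, so every downstream method is
validated on synthetic datasets with known ground truth; the composition
statistics are additionally checked against published group summaries, which
are recomputable from (mean, SD, n) alone.

## Synthetic data generator (`simulate`)

The generator emulates the experimental design: 2 breeds × 6 biological
replicates × 500 nuclei (defaults; all configurable), 11 muscle cell types
(myofiber, FAP, FAP-1, satellite cell, adipocyte, vascular and lymphatic
endothelium, pericyte, macrophage, T cell, B cell) distributed over 16
clusters, 2,000 genes including 20 planted marker genes per type
(log₂FC = 2), 10 mitochondrial genes, and a 14-gene focal KLF panel
(KLF1–KLF13, KLF15 — the bovine family has no KLF14/16/17/18 ortholog).

**Count model.** Counts are gamma–Poisson (negative binomial):
`count ~ Poisson(Gamma(1/δ, δ·μ))` with `μ = L_c · p_{g|type,breed}`, so
`Var = μ + δμ²`. Defaults: dispersion δ = 0.3 (a typical gene-level value
for droplet data), library size `L_c ~ LogNormal(ln 1500, 0.3)`. No
generative model is implied by the study itself; the negative binomial is
the standard overdispersed model for UMI counts.

**Composition.** Per-replicate cell-type proportions are Dirichlet with
breed-specific means (myofiber-rich in ANG, stroma-rich in HST) and a small
concentration (3.0), deliberately producing the large inter-replicate
variability the study reports (myofiber SD comparable to its mean).

**Planted panel effects.** The default breed × cell-type × gene log₂-effect
matrix encodes the study's qualitative patterns: KLF9 (+1.0) and KLF10
(+0.75) HST-enriched across cell types, KLF12 (+0.6) ANG-enriched, KLF6
elevated in lymphatic endothelium in both breeds (+1.5) with an additional
ANG-restricted boost there (+1.2), and a mild whole-panel elevation in
vascular endothelium (+0.8) that drives the module-score ordering. Panel
genes share a fixed baseline relative expression (1.5) so that planted
log₂ effects are directly comparable across panel genes — the condition
under which "largest planted effect" is well defined for recovery tests.

**Mitochondrial content.** Each cell's expected mitochondrial fraction is
3%, except a 5% "bad cell" subpopulation at 15%, giving the QC filter real
work. Mitochondrial genes are named with the `MT-` prefix, which is also how
the reader re-derives the flags.

**What the generator does not emulate.** Doublets, ambient RNA, batch
effects needing integration, gene–gene correlation beyond the planted
type/breed structure, and realistic gene-name-specific biology. Passing
recovery tests therefore demonstrates the statistical machinery is correct
and calibrated, not that the pipeline would reach identical conclusions on
the original tissue data.

## QC and normalization (`qc`)

Nuclei are kept iff `n_features > 200`, `n_counts < 3000` and
`mito_pct < 10` (strict inequalities, exactly as stated; all thresholds
configurable; an optional lower count bound defaults to off). Zero-count
cells define `mito_pct = 0`. Normalization is
`ln(1 + 10000 · count / cell_total)` (natural log, pseudo-count 1; base and
scale configurable). Covariate regression during scaling, HVG selection,
PCA, integration and clustering are out of scope — cluster labels come from
the generator.

## Marker statistics (`diffexpr`)

One-vs-rest per cluster. The Wilcoxon rank-sum statistic is computed from
global ranks (they serve every one-vs-rest split), with a tie-corrected
normal approximation and no continuity correction; clusters with fewer than
3 cells are skipped with a warning. The AUC effect size is `U/(n1·n2)` — the
probability that a random in-cluster cell exceeds a random out-of-cluster
cell. log₂FC uses de-logged group means with pseudo-count 1 inside the
ratio. Genes enter the test only if `max(pct1, pct2) > 0.1`; the Bonferroni
factor is the number of genes actually tested in that comparison (a flag
switches to all genes). DEG filters (all strict): `p_adj < 0.05`,
`|log₂FC| > 0.25`, `max(pct) > 0.1`, `|AUC − 0.5| > 0.1`. Markers rank by
log₂FC descending, ties by smaller adjusted p then gene name.

## Cluster annotation (`annotate`)

For each cluster, the top-25 filtered markers are intersected with each
candidate type's reference marker set; each intersecting gene scores
`log₂FC / max(log₂FC in the top list)` (bounded in (0,1], scale-free) and a
type's score is the sum. The normalization rule was an open design choice;
a sum-normalized variant (`normalization="sum"`) is provided. Assignment is
the argmax; a maximal score of zero yields "unassigned"; exact ties are
flagged and broken lexicographically (a human analyst would resolve them by
literature inspection, which a program cannot).

## Module scores (`genescore`)

The standard expression-binned control construction: genes are placed in 24
quantile bins of mean expression (rank-based, so constant-shift invariant);
each set gene draws 100 controls from its own bin excluding set genes
(with replacement, and a warning, only when the bin is smaller than
requested); controls are pooled, and the per-cell score is mean(set) −
mean(controls). For small universes the bin count is clamped with a
warning. Binning uses the post-QC average over all cells, not per group.

## Composition statistics (`composition`)

Per-replicate cell-type percentages (rows sum to 100) and two-breed
comparisons computed from (mean, SD, n) summaries: Welch's t with
Satterthwaite degrees of freedom and the Welch CI of the mean difference
(the published interval is consistent with Welch df ≈ 8.1, not the pooled
df 10), plus Cohen's d with the classic pooled-SD denominator, which
reproduces the published 0.51. Per-type comparisons are reported without
multiplicity adjustment, matching the descriptive presentation; Bonferroni
and Benjamini–Hochberg adjustments are available behind a flag. A pooled
(Student) variant of the test is also available.

Note on reproducing printed values: from the rounded printed inputs
(32.9 ± 36.1 vs 17.9 ± 21.2, n = 6), Welch gives p = 0.405 and CI
(−24.3, 54.3); the published p = 0.40 and upper bound 54.4 sit within the
propagation band of the ±0.05 input rounding.

## Breed classifier and exact Shapley attribution (`attribution`)

A gradient-boosted tree classifier (depth 3, 200 rounds, learning rate 0.1;
all exposed) is trained on log-normalized panel expression with a
stratified 80/20 split, per cell (the study's unit of analysis and split
protocol are unstated; per-cell with a seeded stratified split is the
documented choice). Performance is the rank-based ROC AUC on the held-out
fold with a stratified percentile bootstrap CI (1,000 resamples).

Attribution is the exact interventional Shapley value on the margin
(log-odds) scale, where tree-ensemble outputs are additive: the value of a
coalition S at cell x is the mean margin over background rows b of the
hybrid input (x on S, b elsewhere), and φ_j is the Shapley-weighted sum of
marginal contributions over all 2^p coalitions (p = 14 → 16,384; a hard cap
of p = 20 keeps enumeration honest). This is model-agnostic and
axiomatically exact — efficiency (base + Σφ = margin) is verified to 1e−6
on every evaluated cell, and the enumeration matches the permutation-form
definition exactly for small p. The background is a breed-stratified sample
of training cells (default 64 rows) and evaluation cells are subsampled
from the test fold (default 500; optionally evenly across cell types for
per-type aggregation). Aggregations: global ranking by mean |φ|, and mean
signed φ per breed and per cell type (positive pushes toward the breed
coded 1, HST). Probability-scale attribution is deliberately not the
default. The stability check intersects the top-k (default 3) global
rankings across ≥3 training seeds.

## Phylogenetics (`phylo`)

Uncorrected p-distance with pairwise gap deletion (Poisson correction
`−ln(1−p)` behind a flag; the study does not state its distance model) and
Saitou–Nei neighbor joining: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, standard branch-length
formulas with negatives clamped to zero, ties broken by the lexicographically
smallest leaf names of the joined subtrees. NJ is exact on additive
matrices, which the tests exploit as an oracle (path lengths on the output
tree must reproduce the input matrix). Clade groups are produced by cutting
the longest branches, internal branches first, until k leaf groups remain —
a formalization of drawing clade boundaries at the deepest splits; the
published three-clade grouping of 62 proteins needs the external sequence
set and is not reproduced at desk scale.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen so the whole
pipeline runs in minutes on a single core while keeping every structural
feature (all 11 types, 16 clusters, planted effects): the 111k-nuclei study
is emulated structurally, not numerically. Multi-seed recovery checks use
20 seeds; the attribution recovery runs at 400 cells/replicate with 60
Shapley evaluation cells and an 8-row background, where the planted-effect
ranking is stable. Ties in marker ranking break by adjusted p then gene
name; degenerate inputs (zero-variance tests, zero-total cells, empty
tables) raise explicit errors or defined values as documented per module.

## Known limitations

- Synthetic validation only for everything the unpublished data would be
  needed for; printed headline numbers that depend on those data (retained
  nuclei, the classifier's AUC = 0.705, specific SHAP magnitudes, clade
  sizes) are treated as qualitative patterns, not targets.
- The annotation scorer consumes any reference marker table but does not
  curate one; decoy corruption only probes robustness.
- Exact enumeration limits the panel to 20 genes; larger panels need
  sampling-based attribution, which is out of scope.
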