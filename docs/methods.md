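# Methods

`hepanet` implements a hub-gene discovery pipeline for paired tumor/normal
expression studies: weighted co-expression network construction, module
detection and module–trait analysis, interaction-neighborhood hub screening,
clinicopathological and survival statistics, and gene-set / immune-infiltration
enrichment.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Sample quality control

Samples are clustered within each tissue class (tumor, adjacent normal) by
average linkage on `1 − r`, where `r` is the Pearson correlation over all
genes.  The tree is cut into a configurable number of groups (defaults: 2
tumor, 3 normal, mirroring the two-group / three-group heterogeneity typical
of paired liver cohorts).  A cluster is retained when its mean intra-cluster
correlation is within `keep_margin` (default 0.05) of the best *substantial*
cluster (≥ 25 % of the tissue's samples).  The margin exists because forcing
a cluster count on homogeneous data splits near-identical groups whose mean
correlations differ by a few hundredths, while genuine outliers (shuffled or
degraded samples) fall far below it.  Singletons are scored by their best
correlation to any other sample, so a near-duplicate split off by the forced
count survives while an isolated outlier does not.  Because the design is
paired, a subject is kept only when both its samples survive; the pass is
iterated to a fixed point, making the operation idempotent by construction.

## Seed-gene selection

Genes are ranked by coefficient of variation, CV = sd/|mean|, computed by
default on linear-scale intensities (`2**x` of the log2 input) where
cutoffs of a few units are meaningful; a `scale="log"` switch computes it on
the values as given.  Both a hard cutoff (default 3.6, appropriate for
linear-scale microarray intensities) and a top-N rank variant are provided;
the pipeline's synthetic default uses top-N 200 because the generator's
intensity scale is not calibrated to any particular array platform.  Genes
with zero mean have undefined CV and are excluded and logged.

## Co-expression network

* **Adjacency.** `a_ij = |cor(x_i, x_j)|^β` (unsigned, default) or
  `((1 + cor)/2)^β` (signed), diagonal forced to 0.  Default `β = 6`, the
  canonical unsigned choice.
* **Soft-threshold diagnostics.** For each candidate power, connectivities
  `k_i = Σ_j a_ij` are binned into 10 equal-width bins on raw `k` (the
  canonical scale-free fit-index convention; log-k binning is available)
  and `log10(frequency)` is regressed on `log10(mean k)`.  The signed fit
  index is `R² · (−sign(slope))`; the recommended power is the smallest one
  reaching the target (default 0.85), else the maximizer.  The pipeline
  reports the table but uses the configured power.
* **Topological overlap.** `ω_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`
  with `l_ij = Σ_u a_iu a_uj`, `ω_ii = 1`; two genes with empty
  neighborhoods and no direct edge get 0.  Verified against a triple-loop
  oracle to 1e−12.
* **Clustering and module cut.** Average linkage on `1 − ω`.  The module
  cut is a deterministic two-phase variant of adaptive dendrogram cutting:
  (1) a static cut at the 0.99 fraction of the merge-height *range* (an
  empirical height quantile is useless here because noise-level merges
  accumulate at the very top); (2) any branch of ≥ 2× the minimum module
  size is re-cut at the same fraction of its own height range, and the
  split is accepted when it yields ≥ 2 viable subclusters all tighter than
  the parent by more than the sensitivity (0.05) in mean internal
  dissimilarity — this peels apart modules joined near the top even when
  stray genes chain onto one of them, while leaving homogeneous branches
  intact.  Clusters below the minimum size (default 30) or with mean
  internal dissimilarity above 0.9 (diffuse, noise-like) are labeled
  `grey`.  Modules are named by size rank along the conventional color
  sequence (turquoise, blue, brown, …).  The reference adaptive tree-cut
  algorithm is deliberately not reproduced label-for-label; recovery of
  planted modules (adjusted Rand index) is the correctness contract.
* **Eigengenes and merging.** The module eigengene is the first right
  singular vector of the gene-standardized module submatrix (unit norm,
  sign-aligned to the module's mean profile); variance explained is the
  first squared singular value over the total.  Modules whose eigengene
  dissimilarity `1 − cor` falls below the merge height (default 0.25) under
  average linkage are merged (label of the largest constituent), iterating
  to a fixed point.
* **Module–trait association.** Pearson `r` between each eigengene and the
  binary tumor/normal trait with the two-sided t-based p-value on `n − 2`
  df.  Module selection for downstream stages ranks by `|r|` by default
  (sign reported); a positive-only mode exists.
* **Edge export.** Undirected pairs with TOM weight above the threshold
  (default 0.1), restricted to the selected modules.

## Hub screening

Co-expression genes (selected-module members) are mapped onto an undirected
protein-interaction network.  For each covered gene with degree ≥ 1 the
screen counts co-expressed (`c`) vs other (`o`) neighbors and computes the
upper-tail hypergeometric probability `P(X ≥ c)` with population `N` (all
network genes), successes `M` (covered co-expression genes), draws `c + o` —
the one-sided Fisher exact test on the corresponding 2×2 table.  The default
multiplicity adjustment is `min(1, M·p)` (Bonferroni-style with the full
covered count as the multiplier), reproducing the convention of the emulated
screening table; Benjamini–Hochberg is available and preferable for new
analyses.  A gene is a hub when its proportion `c/(c+o)` is ≥ 0.10 and its
adjusted p < 0.05.  The focal gene is never counted among its own neighbors
and is not removed from `M` or `N` (a negligible, documented constant at
realistic scales).

## Clinical statistics

Associations between binary clinicopathological covariates and the low/high
expression class use the Pearson chi-square without continuity correction
(1 df) — the uncorrected statistic reproduces the emulated association
table; a correction flag exists.  Immunohistochemistry percent-positive
values map to the 4-level ordinal score (< 25, [25, 50), [50, 75), ≥ 75;
boundaries go to the higher score by default, configurable) with scores 1–2
the low class.  Survival uses the Kaplan–Meier product-limit estimator, the
two-group log-rank test, and Cox proportional-hazards fits via partial
likelihood with Efron's tie correction (the lifelines implementation; on the
tie-free continuous event times simulated here Efron and Breslow coincide).
Continuous expression is dichotomized at the median with ties assigned low.

## Enrichment

* **Two-class GSEA.** Genes are ranked by signal-to-noise
  `(μ₁ − μ₂)/(σ₁ + σ₂)` with each σ floored at `0.2·|μ|` (t statistic and
  log2 fold change available).  The enrichment score is the weighted
  Kolmogorov–Smirnov running-sum extremum with hit weight `|metric|^w / Σ`
  (default `w = 1`) and miss step `1/(n − m)`.  Significance comes from
  phenotype-label permutation (default 1000) when both groups have ≥ 7
  samples, else gene-set permutation; nominal p uses the same-sign null
  with a +1 pseudo-count, NES divides by the mean same-sign |null ES|, and
  q is Benjamini–Hochberg across sets.  A set spanning the entire ranked
  list is rejected (no miss steps exist).
* **ssGSEA.** Per sample, genes are ranked by expression and the score is
  the summed difference between the `rank^α`-weighted in-set ECDF (default
  α = 0.25) and the unweighted out-of-set ECDF; the matrix is divided by
  its global score range when normalization is on.  Raw scores depend only
  on within-sample ranks, hence are invariant to strictly monotone
  per-sample transformations.
* **Immune summaries.** Cell-type marker sets (user-supplied GMT) are
  scored by ssGSEA; Spearman correlation relates each cell type to a key
  gene's expression, and a median-split log-rank/Cox summary relates each
  cell type to survival endpoints.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical shape the analysis assumes, with
defaults fixed at the emulated study's scale: 54 tumor/normal pairs; three
planted co-expression modules of 50 genes at within-module correlation 0.9
among 100 background genes (module eigengene means shifted by 2.0/1.2/0.8
latent-SD units in tumor samples); a 2000-node preferential-attachment
interaction graph (attachment 3) in which 4 genes of the first module
receive 60 extra edges with a 0.3 co-expressed fraction — comfortably above
the ~0.075 background co-expression fraction and at the degree scale of the
emulated screening table — while a rate at or below background yields a null
network; exponential survival with hazard `h₀·exp(β·x)` (defaults
`h₀ = 0.02`/month, `β = ln 2`, 30 % censoring by an independent exponential
clock); and 2×2 clinical covariates with configurable odds-ratio association
to the expression class.  All generators are pure functions of (config,
seed) via named SHA-256 substreams, so stages regenerate independently and
bit-identically.

Not emulated: probe-level artifacts, batch effects, non-exponential hazards,
realistic interaction-network topology beyond scale-free degree structure,
and correlated marker sets.  Passing the planted-recovery tests therefore
demonstrates algorithmic correctness under the assumed generative model, not
performance on any particular real cohort.

## Numerical choices and degenerate inputs

Duplicate expression rows keep the highest-mean row; genes with any missing
value are dropped and counted; zero-variance genes or samples abort the
correlation stages with a named error; an isolated (degree-0) covered gene
is excluded from hub testing; a constant covariate or a degenerate median
split is rejected; table outputs are written at 12-significant-digit
precision so write→read round trips are lossless at tolerance 1e−11.
Cluster ties resolve toward the larger cluster and lower gene index;
all sorts are stable.

## Known limitations

The adaptive tree-cut stand-in has two tuning constants (peel sensitivity
0.05, coherence ceiling 0.9) chosen for clearly separated module structure;
heavily nested or weak modules may require adjustment.  The scale-free fit
index is descriptive, not inferential.  The Bonferroni-with-`M` adjustment
is conservative when many covered genes go untested.  Cox fits assume
proportional hazards and no time-varying covariates; stratified models are
out of scope.
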