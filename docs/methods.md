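# Methods

## Scope and model

`coexdiff` finds disease-related gene modules by requiring two independent
kinds of evidence in two case–control expression datasets measured on
different platforms: a module-level expression change (DE) and a
module-level rewiring of co-expression (DcoE). Within selected modules it
then finds individual genes whose number of extreme-similarity interactions
changes with disease. All statistics are computed per dataset on the
original (non-batch-corrected) matrices; the batch-corrected stacked matrix
serves only to define the network and its modules, so that the module
definition is shared while dataset-specific disease signal is never diluted
by the correction.

## Preprocessing

Quantile normalization maps every sample onto the common reference
distribution (the row-mean of the column-sorted matrix). Ties get the
average of the reference values at the tied ranks; on tie-free input the
operation is exactly idempotent and all sorted columns are identical.
Genes are then ranked by cross-sample SD and the lowest 40% dropped
(`drop_fraction`, configurable; exactly `ceil((1−f)·n)` genes are kept, SD
ties resolved toward the lexicographically larger gene id). When probe-level
data and a probe→gene map are supplied, the probe with the largest mean
expression represents the gene (ties toward the smaller probe id). The
pipeline's order is normalize → filter → collapse; each step is exposed
separately for other orders. Data are assumed log2 scale; `log2_transform`
(log2(x+1)) is provided for linear-scale input but scale is never guessed.

## Batch correction

Parametric empirical-Bayes adjustment of the ComBat family: per gene,
standardize against a model containing batch indicators and (by default)
the disease indicator as a protected covariate; estimate per-(gene, batch)
location (gamma) and scale (delta²); shrink locations toward a normal
batch-level prior and scales toward an inverse-gamma prior fitted by method
of moments; back-transform. Including the condition covariate avoids
erasing disease signal when case/control proportions differ between
batches. Only the parametric variant is implemented; a single-batch input
is returned unchanged. Batches need ≥ 2 samples and genes nonzero pooled
variance.

## Differential expression

Per gene, a two-group linear model gives the log2 fold change
(disease − control) and residual variance s² on d degrees of freedom. The
log-variance ensemble is fitted by method of moments (digamma/trigamma
identities) to a scaled-F model, giving prior df d0 and prior variance s0²;
each variance becomes (d0·s0² + d·s²)/(d0 + d), and the moderated t is
referred to t on d0 + d df. If the ensemble shows no excess spread, d0 = ∞
(fully pooled variance, normal reference); a single gene has no ensemble
and falls back to the ordinary t-test. FDR control is Benjamini–Hochberg.
Genes with adjusted p < 0.05 are DEGs, with raw p < 0.05 "possible DEGs" —
in underpowered blood studies the latter set is the practical one.

## Network construction

* **Correlation**: biweight midcorrelation, with weights
  w = (1−u²)²·1[|u|<1], u = (x − median)/(9·MAD). Genes with zero MAD fall
  back to Pearson for every pair they join (the biweight is undefined
  there); constant genes get correlation 0 off-diagonal.
* **Adjacency**: a = |bicor|^β by default; a signed variant
  ((1+r)/2)^β is available behind `signed_adjacency` since the powering
  convention on signed correlations is a known ambiguity of the method
  family.
* **Soft threshold**: for each candidate power, connectivities are binned
  into 10 equal-width bins and log10(frequency) is regressed on
  log10(mean k); the fit index is −sign(slope)·R². β is the smallest power
  with index > 0.8. Powers that collapse the network below a mean
  connectivity of 1 are excluded from the choice: any thresholded network
  looks scale-free once almost all edges vanish, so without this floor the
  criterion degenerates on modular-but-not-scale-free inputs. If no
  eligible power passes, the best-fitting one is returned with a warning
  flag.
* **TOM**: TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diag
  treated as 0 internally and set to 1; dissimilarity is 1 − TOM.

## Module detection

Average-linkage clustering of the dissimilarity, then a top-down hybrid
tree cut reimplemented for behavioural (not bit-exact) parity with the
reference algorithm:

* `max_dissimilarity` m defines the cut-height ceiling
  h = h_min + (1−m)(h_max − h_min) over the dendrogram's merge heights;
  branches merging above it are separate subproblems.
* A branch becomes a module if it has ≥ `min_module_size` leaves and its
  core scatter — the mean merge height inside the branch, i.e. on the same
  scale as the cut height — is below a ceiling interpolated between the 5%
  height quantile and the cut height by a fraction q(deep_split) taken from
  (0.64, 0.73, 0.82, 0.91, 0.95). Merge heights are used rather than raw
  mean pairwise dissimilarity because TOM dissimilarities compress toward 1
  and must be judged relative to the dendrogram, not absolutely.
* Two sub-branches are split apart when both are large enough and the merge
  gap exceeds 0.75·(1−q)·(cutHeight − h05); larger deep_split therefore
  splits more aggressively and accepts looser cores, monotonically.
* The PAM rescue stage is off: genes on no accepted branch are "grey".
  Modules are labelled by size rank on the conventional color list
  (turquoise, blue, brown, ...).

**Consensus**: partitions are computed for all 60 grid cases
({50,60,70,80,90,100} × {0..4} × {0.1,0.2}); each module of each case is
scored by the fraction of cases containing a module with Jaccard ≥ 0.5, and
the case with the most modules stable in > half of the cases wins (ties →
smaller deep split, then larger minimum size). The dendrogram is computed
once and only the cut varies, so the grid costs little.

## Module selection (DE + DcoE)

The module eigengene is the first right-singular vector of the
gene-standardized module submatrix, unit norm, sign-aligned with the
module's mean profile; OLS of the eigengene on the disease indicator gives
the DE beta and p. Condition-specific adjacency matrices are rebuilt per
dataset with the combined network's β; intramodular connectivity is the
adjacency row-sum over module genes (self excluded); the paired t-test on
per-gene (disease − control) connectivity, Bonferroni-corrected over the
number of modules tested, gives the DcoE decision with direction GOC/LOC.
A module is selected iff DE p < 0.05 in ≥ 1 dataset and DcoE Bonferroni
p < 0.05 with the same direction in both datasets. Whether expression and
connectivity move concordantly (up+GOC / down+LOC) is recorded but not
required.

A caution the paired test inherits from its field: connectivities of
co-expressed genes are strongly dependent, so the t statistic's magnitude
is much larger than its nominal null distribution suggests. The dual
criterion (direction agreement across two independent datasets plus DE)
is what keeps the family-wise error of *selection* controlled — measured
type-I selection of null sibling modules is ≈ 3% in the acceptance
simulation — while a single paired test in a single dataset should not be
read at face p-value.

## Gene selection

Within a selected module, per dataset and condition, the module submatrix
goes through bicor → power β → TOM → dissimilarity. Gene pairs below
mean − 3·SD of that matrix's upper triangle (sample SD, each pair once)
are interactions. Per gene, Δ = interaction count in disease − control and
Z = (Δ − mean)/SD within the module (population SD, so Z has unit SD).
A gene is selected when |Z| ≥ 2 in ≥ 1 dataset with sign matching the
module's direction, and its fold-change sign is identical in both datasets
and matches the module's expression direction. The Z cut-off is a
parameter: published use of this criterion has varied between 1 and 2, and
2 is the conservative default.

## Replication

Candidates are tested in an independent dataset without rebuilding a
network: Spearman correlation matrices over the module's genes are computed
per condition, per-gene connectivity is the signed correlation row-sum
(option `use_abs` for |r|), and the module-level GOC/LOC call reuses the
paired t machinery. A candidate replicates when its connectivity-change
direction matches the derivation call *and* it is dysregulated in the
independent dataset in the derivation direction (moderated DE, FDR p < 0.05
with matching sign). Direction concordance alone would agree with chance
with probability 1/4, which is why the significance condition is part of
the flag. Genes absent from the independent dataset are "untestable", not
failures.

## Enrichment

Hypergeometric upper tail of the candidate/pathway overlap against the
background of genes surviving preprocessing, computed in log space;
pathway members outside the background are dropped before testing; BH
correction across pathways, significance at adjusted p < 0.05. GMT is the
input format.

## Synthetic studies

The generator plants each module as an equicorrelated block from one latent
factor per condition: x = √ρ·f + √(1−ρ)·ε, so the population pairwise
correlation is exactly ρ. Designated DcoE modules switch ρ from
`base_corr` to `dcoe_corr` in disease; DE modules add `de_shift` (log2) to
disease samples; hub genes (in the DcoE modules by default) have their
loading raised to `hub_loading` in disease only, producing the
extreme-similarity edge asymmetry the gene stage detects. Per-gene
baselines are N(7, 1) on the log2 scale and per-gene expression scales are
log-normal (`gene_scale_sd`, default 0.3) — without scale heterogeneity the
SD filter would remove genes at random per dataset and destroy the
cross-dataset gene intersection, which is not how real transcriptomes
behave. Every dataset after the first receives per-gene additive offsets
N(0, `batch_gamma`²) and multiplicative deviation factors
exp(N(0, `batch_delta`²)), the ComBat model family. Everything is driven by
one `numpy` Generator seed; identical configs give bitwise-identical
output.

What the generator does *not* emulate: probe-level artifacts, platform-
specific probe IDs, heavy-tailed or count-type noise, correlated background
structure, and confounding between batch and condition. Passing tests on
this generator therefore show that the machinery recovers the planted
signal under the stated model, not that any particular real study's gene
lists would be reproduced.

## Study conditions used by the tests and the acceptance script

Simulation sizes were chosen so the whole suite runs in minutes on one
core while keeping each check statistically meaningful:

* Batch correction: 1000 genes, 50+50 samples, additive offsets of scale 2.
* Module recovery: 4 modules (150/120/100/80) among 1000 genes, ρ = 0.6,
  100 samples, full 60-case consensus.
* DcoE power/type-I: two 50-gene modules among 120 genes, ρ 0.3 → 0.7,
  shift 0.5, 50+50 samples × 2 datasets, 100 replicates.
* Hub recovery: one 300-gene module, 20 hubs with loading 0.55 → 0.9,
  60+60 samples × 2 datasets, 100 replicates.
* End-to-end demo: 800 genes, two 250-gene modules, 50+50 × 2 datasets,
  ρ 0.6 (→ 0.7 in the signal module), shift 1.0, 5 hubs at loading 0.97,
  batch γ = 1, δ = 0.2. Quantile normalization and cross-batch stacking
  attenuate intra-module correlation by roughly 0.1–0.2, and hub genes are
  only separable as extreme-similarity outliers when their loading clearly
  exceeds the module's disease-condition loading; the demo values are the
  weakest round numbers at which every stage has something real to find at
  this scale.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1] and matrix symmetry is enforced by
averaging with the transpose where float error could break it. TOM entries
are clipped to [0, 1]; 0/0 cells (isolated gene pairs) become 0. A constant
eigengene yields (beta 0, p 1) with a warning; an all-zero connectivity
difference yields (t 0, p 1); a constant dissimilarity matrix yields zero
edges (strict inequality against mean − 3·SD); fewer genes than
`min_module_size` yields an all-grey partition with a warning. BH-adjusted
values are capped at 1 and monotone in rank order. The ComBat
posterior-mode iteration stops at relative change 1e−4.

## Known limitations

* The paired DcoE t-test ignores gene–gene dependence (see above); its
  p-values are calibrated only through the multi-dataset selection rule.
* The hybrid tree cut matches the reference algorithm behaviourally, not
  label-for-label; comparisons with other implementations should be made
  via partition similarity (ARI), not string equality.
* Only two-group designs (disease vs control) are supported throughout; no
  covariates in the DE model, no multi-factor batch designs.
* Networks beyond ~5000 genes are quadratic in memory (dense matrices);
  no block-wise approximation is provided.
* The equicorrelated single-factor block is a deliberately simple module
  model; real modules have nested correlation structure that makes both
  detection and tree-cut stability harder than in these simulations.
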