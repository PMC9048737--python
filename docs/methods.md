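# Methods

This note documents the models and procedures implemented in `dysbiom`,
the defaults they ship with, and what the synthetic benchmark does and does
not establish.

## Study design being modeled

The package targets three-group fecal 16S case-control designs: an
infected case group (FRI), a disease control group that shares the
fracture history but not the infection (FH), and healthy controls (HC),
with per-sample covariates (age, sex), an optional case subgroup flag
(sinus tract / visible pus), and serum inflammatory markers (NEU, ESR,
CRP, SAA, WBC, IL-6, TNF-α, UA, VD, Glu, PCT). Group sizes default to
20/18/12, the cohort scale this class of study operates at.

## Feature table handling

Counts are taxa × samples integer tables. Collapsing to a rank sums rows
sharing the lineage prefix through that rank; taxa unnamed at the rank are
pooled per parent into `unclassified_<parent>`, and homonymous genera from
different parents are disambiguated with the parent name. Column sums are
preserved exactly.

Relative abundance divides each sample column by its total; no
rarefaction is applied by default. Whether to subsample to even depth is
left to the user (`feature_table.subsample_even_depth`), since diversity
comparisons on full columns and on rarefied columns answer slightly
different questions; all shipped analyses use full columns.

The differential-genus prefilter keeps a genus iff its relative abundance
reaches `min_rel` (default 10⁻⁴, i.e. 0.01%) in at least `min_prev`
(default 20%) of samples, both boundaries inclusive. The phrase "remove
low abundance and prevalence" is implemented as the complement: retention
requires reaching the threshold, which is the conservative reading for a
filter meant to remove noise taxa. Filtering never renormalizes.

## Diversity

* **Shannon index**: −Σ pᵢ log pᵢ over nonzero proportions, log base 2 by
  default (bits); the base is a parameter because conventions differ.
* **Faith's PD** is the "whole tree" variant: the total branch length on
  the union of root-to-tip paths of observed taxa, root path included.
  Empty samples return 0 by convention.
* **UniFrac**: unweighted (unique / union branch length over descendant
  presence) and weighted. Weighted defaults to the normalized variant so
  the distance is bounded in [0,1]; the raw variant is available.
* **PCoA**: Gower double-centering of −½d², full eigendecomposition.
  Negative eigenvalues (non-Euclidean distances) are reported and excluded
  from the proportion-explained denominator; no correction is applied
  unless the Cailliez additive constant is requested.
* **PERMANOVA**: Anderson's distance-based pseudo-F with a label
  permutation null, p = (1 + #{F\* ≥ F}) / (1 + permutations) so p is
  never zero; 999 permutations and an explicit seed by default.

Faith's PD, UniFrac, PCoA and PERMANOVA are computed with scikit-bio
behind this module's surface; the test suite cross-checks UniFrac against
a brute-force edge enumeration on small random trees, PERMANOVA against
exhaustive label enumeration at n = 6, and PCoA against hand-computed and
metric-recovery cases.

## Biomarker discovery

**LDA effect size.** Genera passing a tie-corrected Kruskal–Wallis screen
(α = 0.05, no multiplicity correction — deliberately, as a screen) are
rescaled to parts per million and scored one-vs-rest against the group
where their mean is largest. Over 30 bootstraps (stratified 2/3
subsamples, seeded), a linear discriminant is fitted on all passing
features; the per-feature effect is the average of (a) the absolute
between-class mean difference and (b) the feature's contribution along the
unit discriminant axis, |wⱼ|·|w·Δm|. The score is log₁₀(1 + mean effect),
signed positive toward the case group, thresholded at 2.0. Only the
ranking and sign behaviour of this score is contractual; the per-bootstrap
formula is pinned in code comments and verified through planted-effect
recovery and monotonicity tests rather than score equality with any
external tool. A singular within-class scatter falls back to a
shrinkage-regularized solver (shrinkage 10⁻³) instead of failing.

**GLM differential abundance.** Per genus, a negative-binomial regression
of raw counts on `group + age + sex` with a log library-size offset;
two-sided Wald p for the case-group coefficient (HC, or FH in the FRI-vs-FH
pair, is the reference level). Dispersion is estimated by joint maximum
likelihood; on non-convergence the Cameron–Trivedi method-of-moments
estimate is plugged into an NB GLM, and pathologically sparse genera fall
back to the Poisson fit (flagged `converged=False`). Poisson and
presence/absence-binomial families are available for sensitivity checks.
NB Wald tests are known to be mildly anti-conservative at small n; the
calibration tests therefore check the type-I rate at n = 200 samples,
where the test operates within the nominal band.

**Signature construction.** Three modes: `lefse` (passing genera
partitioned by their enriched group), `glm-union` (union of genera with
p < 0.05 across the three comparisons, assigned to the case side iff the
case-group mean relative abundance exceeds the pooled-control mean, ties
going conservatively to the control side), and `manual` (externally given
4 + 10 genus lists, validated against the table). Because the union of
three uncorrected 5%-level tests over ~100 genera necessarily admits
false positives, the `lefse` mode — double-gated by the screen and the
LDA threshold — is the default for signature discovery, and the GLM route
serves as the covariate-adjusted confirmation, mirroring how the two
methods are ordinarily combined.

## Dysbiosis index and evaluation

DI = (case-enriched mass + ε) / (control-enriched mass + ε), ε = 10⁻⁶
applied symmetrically so the index stays finite on zero denominators and
side-swapping maps DI → 1/DI exactly. Rank tests operate on the raw scale
(they are monotone-invariant); log₁₀(DI) is written alongside for
inspection.

ROC curves sweep every observed threshold; AUC equals the Mann–Whitney
concordance with ties counted ½. Group tests: exact rank-sum enumeration
when both groups have ≤ 10 samples and no ties, tie-corrected normal
approximation otherwise; Pearson χ² without continuity correction; one-way
ANOVA; Kruskal–Wallis as above.

**Composition classifier.** A logistic model on standardized
log₁₀(relative abundance + ε) of the signature genera. The cross-validated
AUC uses **leave-pair-out**: every (case, control) pair is held out, the
model refitted, and the AUC is the fraction of held-out pairs ranked
correctly. Leave-one-out was rejected after measurement: under label
permutation its mean AUC sits near 0.43 regardless of n (the held-out
sample's class is anti-correlated with the training class balance, a
documented small-sample pathology of LOO AUC), whereas leave-pair-out is
unbiased (measured 0.49–0.51 under the same null). LOO and resubstitution
remain available as options; for leave-pair-out the returned ROC curve is
descriptive (mean held-out scores) while the `auc` field is the pairwise
estimate. Suspected separation (non-convergence at C = 10⁶) falls back to
a ridge-penalized fit and is logged.

Odds ratios are univariate logistic fits per serum marker (standardized
by default so ORs are per-SD; raw scale available) with Wald 95% CIs;
perfect separation falls back to a ridge-penalized point estimate with the
CI withheld and the row flagged. Marker–taxon association uses
tie-corrected Spearman ρ with Benjamini–Hochberg adjustment across the
whole grid; raw p-values are always emitted alongside.

## Synthetic data generator

Per sample: library size ~ negative binomial (mean 20 000, size 5);
composition ~ Dirichlet with total concentration 100 over lognormal
per-taxon weights; counts ~ multinomial. Planted (taxon, group, log₂FC)
effects multiply that group's concentration by 2^FC; the default scenario
plants +3 on the 4 case-enriched genera and −3 on the 10 control-enriched
genera in the case group. ±3 log₂ was fixed once as the "strong effect"
study condition: these cohorts report highly significant separations and
near-perfect AUCs, which only materialize at effects of this order at
n ≈ 50. A `richness_deficit_frac` (default 0.25) of background taxa is
additionally zeroed in the case group's concentration vector, producing
the reduced richness and Faith's PD such cohorts show. Signature taxa
draw their base weights from a tighter, higher lognormal than background
taxa, reflecting that real signature genera are common gut genera — and
ensuring they survive the prevalence filter.

Serum markers are generated per (marker, taxon, target ρ) link: the
taxon's relative-abundance ranks are mapped to normal scores, mixed with
Gaussian noise at Pearson r = 2·sin(πρ/6) (the Gaussian-copula inverse of
Spearman's ρ), and passed through a monotone lognormal transform. Spearman
correlation is rank-based, so the transform is free and the target ρ is
hit up to sampling noise. Default links couple inflammatory markers
positively to case-enriched taxa (|ρ| 0.4–0.6) and negatively to
control-enriched taxa (|ρ| 0.3–0.5).

The taxonomy assigns signature ASVs their genus names and gives filler
ASVs numbered genera, with some genus sharing and some missing-genus
lineages so rank collapsing is genuinely exercised. A random
coalescent-style binary tree with exponential branch lengths supplies the
phylogeny.

**What the generator does not emulate:** real phylogenetic correlation
between ecologically related taxa (the tree is random, so planted effects
are phylogenetically unstructured), antibiotic exposure, batch or
sequencing-depth artifacts, zero-inflation beyond the
Dirichlet-multinomial's own, or subject-level covariate confounding (age
and sex are independent of group). Passing the planted-effect benchmarks
therefore demonstrates that the statistical machinery recovers known
structure at cohort scale — not that any particular real cohort's effect
sizes are attainable.

## Benchmark scenarios and problem sizes

* **Null calibration**: 200 generator datasets with nothing planted;
  Kruskal–Wallis and PERMANOVA are checked at cohort scale (20 samples),
  the NB GLM at n = 200 samples (see above); all must fall inside the
  binomial 95% band around 5%.
* **Planted recovery**: the Jaccard benchmark disables the richness
  deficit (`richness_deficit_frac = 0`) so ground truth is exactly the 14
  planted genera — with the deficit on, the dropped background taxa are
  *also* genuinely differential and the detector correctly flags them,
  which would contaminate a recovery measure aimed at the signature. The
  LEfSe-mode signature must reach median Jaccard ≥ 0.6 over 10 seeds; the
  DI ordering (FRI above both controls, rank-sum p < 0.05) must hold in
  ≥ 8/10 seeds at full defaults; the leave-pair-out composition AUC must
  reach 0.9 on the strong-effect scenario.
* **Determinism**: a full pipeline rerun under the same configuration must
  reproduce every output checksum; all randomness flows from explicit
  seeds (stage seeds are derived from the run seed with fixed offsets).

## Known limitations

* The LDA effect size follows the published recipe's shape but is not
  numerically identical to any external implementation; compare rankings,
  not scores.
* NB Wald p-values are anti-conservative below a few dozen samples per
  group; treat the GLM route at cohort scale as confirmatory, not as an
  error-controlled discovery procedure (the uncorrected three-comparison
  union inflates false positives by construction).
* The dysbiosis index depends on the signature's composition; indices
  built from different signatures are not comparable in absolute value.
* PCoA proportions explained are computed over positive eigenvalues only;
  with strongly non-Euclidean distances consider the Cailliez correction.
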