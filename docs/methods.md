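# Methods

This note documents the statistical machinery implemented in
`enrichprs`, the assumptions behind it, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate.

## The analysis model

The workflow targets a phenotype — chronic post-surgical pain (CPSP),
an NRS pain score at 6–12 months after surgery, dichotomized at > 3 —
measured in a cohort far too small for GWAS. Statistical power is
recovered by restricting attention to a *case universe* of genes: a
literature-curated training set plus a list of candidate genes totally
ordered by functional similarity to that training set. All genes
outside the case universe form the control pool.

**Association.** Each variant is tested by OLS of the continuous NRS
outcome on the additive-coded genotype (major homozygote 0,
heterozygote 1, minor homozygote 2) plus the non-genetic covariates
that pass a univariate screen at p < 0.1 (strict). Self-reported race
is carried as a covariate rather than ancestry principal components.
The scan is implemented as batched normal-equation OLS with per-variant
downdating for missing genotypes; it is algebraically exact OLS and is
cross-checked against statsmodels fit by fit in the test suite. No
multiple-testing correction is applied at this stage: the nominal
p < 0.05 count is the *statistic* consumed by the enrichment test,
whose resampling null provides the error control by construction.

**Enrichment.** Cumulative variant sets are built along the candidate
ranking: set 0 is the training-gene variants; set k adds the variants
of the top ⌈k·10%⌉ candidate genes (ceiling, so the 100% set always
covers the full universe). For each set, the observed number of
variants with p < α (α = 0.05) is compared to the same count in 10,000
control draws matched to the case set's minor-allele-frequency profile
over four bands — [0.10, 0.15), [0.15, 0.20), [0.20, 0.30),
[0.30, 0.50] (left-closed, top band closed). The empirical p-value is
`#{null ≥ observed} / 10,000` with no add-one correction (a
Davison–Hinkley-corrected variant is available behind a flag), and a
set is *enriched* when the observed count exceeds the null's 95th
percentile. The *minimal enriched set* is the earliest enriched
centile; its variants feed selection.

Within a draw, control variants are sampled without replacement within
each MAF band. Because bands are disjoint strata and only the count of
significant variants matters, the null count is exactly a sum of
independent per-band hypergeometric variables; the implementation
draws the null in that form, which makes the 10,000-run test O(bands)
instead of O(pool) per run with an identical distribution.
`draw_matched_control` materializes explicit matched variant sets under
the same contract when the sets themselves are wanted. Each cumulative
set gets an independent substream of the seed; draws are never reused
across centiles.

**Selection and PRS.** Variants of the minimal enriched set (after
modal imputation within self-reported ancestry groups — a deliberate
stand-in for reference-panel imputation, which is out of scope) enter
two L1-penalized regressions over unstandardized additive codes: LASSO
linear on the continuous outcome and L1 logistic on the dichotomous
outcome, each with its penalty chosen by 10-fold cross-validation at
the CV-error minimum (deviance scoring for the logistic model). The
selection is the intersection of the two non-zero supports. PRS
weights are *not* the LASSO coefficients: each selected variant
re-uses its single-variant covariate-adjusted linear coefficient
`b_i`, oriented so the risk allele is the minor allele when `b_i > 0`
and the major allele otherwise, with weight `|b_i|`. The score is the
exact weighted risk-allele sum, bounded by [0, 2·Σ|b_i|].

**Prediction and validation.** The clinical model is forward-stepwise
logistic regression (entry/retention at Wald p < 0.05); the genetic
model adds the PRS to the retained clinical terms. Discrimination is
the rank-based AUC (Mann–Whitney form) with DeLong asymptotic
confidence intervals, and the two models are compared by the paired
DeLong test — the standard equivalent of a SAS ROC contrast. Internal
validation refits the fixed final model on 1,000 bootstrap resamples
(same size, with replacement; single-class resamples are redrawn so the
count stays fixed): per term we report the bootstrap mean, the bias
(bootstrap mean − original), the bias-corrected coefficient (original
− bias, an exact identity), a percentile 95% interval and the OR
equivalents.

**Power calculations.** Three design calculations are provided:
(1) a one-sided two-sample proportion comparison with pooled-null /
unpooled-alternative normal approximation and no continuity correction
(e.g. a background association rate of 0.05 vs 0.064, OR 1.3, at 3,310
variants per group gives power ≈ 0.79); (2) a two-sided two-sample
mean comparison with common SD (a PRS difference of 2 at SD 4 between
groups of 52 and 79 gives ≈ 0.80); and (3) Monte-Carlo power of the
additive single-variant case-control test: controls draw
Hardy-Weinberg genotypes at the given MAF, cases at the allele
frequency whose odds are OR-fold the control odds, and each replicate
is tested by a logistic Wald test (vectorized Newton–Raphson on
genotype-aggregated counts, verified against statsmodels). The
case/control split defaults to 53/78.

## The synthetic cohort generator

`SimConfig`/`simulate_cohort` emulate the target data structure:

- **Genotypes**: per-variant MAF uniform on [0.10, 0.50]; within-gene
  LD via a Gaussian copula whose latent normals follow an AR(1) with
  coefficient `ld_rho` (default 0.3 — the real within-cohort LD level
  is unknown, so this is a knob for exercising the pruner, not an
  estimate), thresholded at the cumulative HWE probabilities. At
  `ld_rho = 0` genotypes are exact HWE multinomial draws.
- **Outcome**: NRS = intercept + Σ β·(risk-allele count) +
  0.147·CASI + N(0, 2.0), clipped to [0, 10]; the intercept is set
  from the empirical quantile of the linear predictor so that the
  realized prevalence of NRS > 3 matches the 40% target (monotone in
  the target; unattainable targets — e.g. a threshold outside the
  clipped range — raise a diagnostic error).
- **Covariates**: CASI is truncated normal (mean 28.55, SD 5.53,
  range 18–54); the remaining clinical columns (preoperative pain,
  demographics, surgical duration, anesthetic doses, acute-pain
  summaries) are drawn at realistic scales and are pure noise unless
  an effect is configured.
- **Missingness**: completely at random at 2% (the rate implied by 45
  missing cells among 131×16 genotypes in the motivating cohort).
- **Defaults** are the study conditions: 131 individuals, 31 training
  genes, 1,305 ranked candidates, 40% prevalence, with 20 planted
  training-gene effects of 0.8 NRS per allele. The control pool
  (3,000 genes) and per-gene variant count (3–8) are desk-scale: large
  enough that every MAF band can match the full case universe, small
  enough that a hundred full simulate→QC→associate→enrich cycles run
  in minutes on one core. All randomness flows from one seed through
  named substreams (structure, genotypes, effects, phenotypes,
  covariates, missingness), so any stage is independently
  reproducible and a fixed seed reproduces the cohort byte for byte.

What the generator does *not* emulate: population structure and
admixture, reference-panel imputation uncertainty, genotyping-array
intensity artifacts, informative missingness, and realistic inter-gene
LD. Tests passing on these cohorts therefore demonstrate the
*statistical mechanics* of the workflow — calibration of the
resampling null, recovery of planted aggregate signal, exactness of
the score arithmetic, directionality of the AUC gain — not performance
on real genotype data, where LD structure and confounding are harsher.

## Numerical and design choices

- **LD pruning dialect**: within each 50-variant window (step 5), while
  any retained pair has r² > 0.8, the member with the lower MAF is
  dropped (ties: the later position). Windows never span chromosomes;
  r² uses pairwise-complete observations, and a zero-variance vector
  yields r² = 0 with a warning.
- **Exclusion order** is fixed and reported per criterion:
  non-autosomal → gene-less → call rate → HWE → MAF, so exclusion
  counts are reproducible; the filter is idempotent.
- **HWE** uses the 1-df χ² goodness-of-fit approximation (monomorphic
  variants: p = 1 by convention). Its agreement with the exact
  conditional (Levene–Haldane) test is verified in the
  moderate-departure regime; for extreme departures at small n the χ²
  approximation is anti-conservative relative to the exact test, which
  is immaterial at the 1e-4 screening threshold.
- **Stepwise fits** detect (quasi-)separation by convergence checks and
  report it as an explicit error rather than returning inflated
  coefficients.
- **Untestable variants** (zero genotype variance, or fewer than 10
  complete cases) carry β = 0, p = 1 and a flag, and are barred from
  PRS orientation (|β| = 0 would be meaningless).
- **Bootstrap resamples** with one outcome class are redrawn, keeping
  the resample count fixed; more than 10% redraws triggers a warning.
- **Penalized-model solver**: the logistic arm uses saga with an
  unpenalized intercept and deviance-based CV scoring; columns are
  left unstandardized (additive codes share a scale), with a flag to
  standardize.
- **Probability curve**: delta-method intervals on the logit scale,
  mapped through the inverse logit; the 50%-crossing PRS is the closed
  form −(intercept + fixed-term contributions)/β_PRS and is reported
  as undefined when β_PRS = 0.

## Problem sizes used in the shipped checks

The test suite and acceptance script size their simulations for a
single CPU: the resampling-null calibration runs 400 independent
10,000-draw tests on uniform p-values; minimal-set recovery runs 100
full cohort cycles at the generator defaults; the end-to-end AUC
direction check runs the complete pipeline on 50 planted-signal
cohorts of 300 individuals (the size at which the paired AUC
comparison itself has high power); the Monte-Carlo power target uses
5,000 replicates. The dual-LASSO recovery and null-selection checks
use 50 seeds at n = 500 with ~100 candidate variants.

## Known limitations

- The enrichment statistic is self-contained (non-competitive): it
  asks whether case-gene variants beat frequency-matched random
  variants, not whether they beat other gene sets of the same size and
  structure; gene-level statistics are out of scope.
- LASSO selection among correlated variants is unstable by nature
  (the intersection rule inherits L1 degeneracy); stability is only
  asserted for near-orthogonal designs.
- PRS weights are in-sample: without an external validation cohort the
  reported AUC of the genetic model is optimistic, and the bootstrap
  quantifies only part of that optimism (coefficients, not variant
  selection, are revalidated).
- The modal-genotype imputer is a deliberately simple stand-in; it is
  adequate at ~2% missingness with common variants but is not a
  substitute for haplotype-based imputation at scale.
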