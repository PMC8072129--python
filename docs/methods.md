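# Methods

This note documents the models, conventions and numerical choices behind
`fldscreen`, and what the synthetic experiments do and do not demonstrate.

## The synthetic cohort generator

The generator emulates the statistical structure of a hospital
physical-examination database with ultrasound-confirmed fatty-liver labels.
It is first-class, tested code: the study conditions for every downstream
check.

**Demographics.** `sex ~ Bernoulli(male_fraction)` (default 0.55, reflecting
the male excess typical of exam cohorts); age is a three-component truncated
normal mixture — (weight 0.25, 30 ± 9), (0.45, 46 ± 11), (0.30, 65 ± 9)
years — truncated to `age_range` (default 18–95) and rounded to whole years,
as exam records store it. Integer ages also keep ChiMerge's
one-bin-per-distinct-value initialisation small.

**Analytes.** Six core analytes (TG, ALT, AST, GGT, UA, GLU) are log-normal
with physiological locations (e.g. TG ≈ 1.3 mmol/L, ALT ≈ 24 U/L,
UA ≈ 330 µmol/L), small age slopes and male–female contrasts on the log
scale, and a fixed latent correlation structure (AST tracks ALT at ρ = 0.75;
GGT weakly tracks ALT; UA and GLU weakly track TG). Noise columns are
log-normal draws independent of everything, with per-column parameters fixed
by an internal constant so "the default cohort" means the same columns under
every seed. All locations and scales are package defaults, configurable, and
not estimates of any particular dataset: real exam data are only available
to us as published summary figures.

**Label.** A latent score
η = β₀ + β₁·TG + β₂·log ALT + β₃·GGT + β₄·GLU + β₅·age_z,
age_z = (age − 47)/16, with y ~ Bernoulli(logistic(η)). The default
coefficients (1.8, 2.5, 0.026, 0.74, 0.74 in the analytes' natural units)
were chosen once, at design time, by Monte Carlo so that the Bayes score η
separates cases from controls with AUC ≈ 0.92 — the regime in which a
boosted model on the observed features plateaus in the high 0.80s/low 0.90s,
i.e. a realistically strong but imperfect biochemical signal. Because η is a
*nonlinear, multi-analyte* function (raw TG plus log ALT), no single raw
column carries the full signal, which is precisely what gives the symbolic
feature search something to find.

**Intercept calibration.** β₀ solves mean(logistic(β₀ + slope)) = target
prevalence (default 0.23) by bracketed Brent root search over a fixed
50,000-draw calibration sample; the mean is strictly increasing in β₀ so the
root is unique, and with all slopes zero the solution is exactly
logit(target). Calibration uses its own seed substream, so generation is
bit-reproducible per (config, seed).

**Missingness** is injected completely at random per column (default rate
0.12), with the last two feature columns forced to ≥ 0.95 missing to emulate
rarely-ordered exam items. MCAR is the weakest mechanism consistent with
median imputation; real exam missingness is plausibly informative
(missing-not-at-random), which this generator does not emulate — see
Limitations. A small fraction (default 2%) of rows get no ultrasound label,
so the filtering stage has real work.

## Preprocessing

Features missing in more than ⅔ of patients are dropped (an absolute-count
variant is available). The split takes exactly round(0.7·n) training rows;
stratification uses per-class largest-remainder allocation, so each class's
training count is within one sample of its proportional share. The
per-class summary tests each feature against the label with a chi-square
independence test on a 4-bin quartile discretisation of the pooled observed
values — a deliberate convention that makes "chi-square test on a continuous
feature" well-defined; features with fewer than 8 observed values or
degenerate quartiles are reported untested. No multiple-testing correction
is applied, matching screening-table practice.

## ChiMerge binning

Classic bottom-up ChiMerge against the binary label: initialise one bin per
distinct value; merge the adjacent pair with the smallest chi-square; stop at
the requested bin count (default 5). Conventions fixed here: the *leftmost*
minimal pair wins ties; zero-expected cells contribute zero (so empty bins
merge first); intervals are right-closed with unbounded outer edges, making
bin assignment total for any finite value, including unseen test-set ages.
Internally the 2×2 statistic is computed exactly as the integer ratio
N(ad − bc)²/(R₁R₂C₁C₂) and pairs are compared by cross-multiplication:
mathematically tied pairs are *exactly* tied, so the leftmost rule is decided
by arithmetic rather than floating-point rounding. The test suite verifies
exact agreement with an independent exhaustive greedy oracle in rational
arithmetic, ties included.

## Group-median imputation

Medians of observed training values per (age-bin, sex, feature) cell; even
counts use the mean of the two central order statistics. Application is a
total function via the fallback chain cell → sex → global median (the
fallback is our choice; some rule is mandatory for empty cells). The plan is
fitted on training rows only and applied frozen to the test set —
deliberately leak-free even though the original workflow's ordering is not
documented. Features never observed in training are flagged unusable and
dropped by the pipeline.

## Symbolic feature synthesis

Expression trees over feature names with unary {log, sqrt} and binary
{+, −, ×, ÷} operators; depth is the edge count of the longest root-to-leaf
path, bounded at 3 (≤ 8 leaves), with unary operators counting toward the
budget. Protected semantics make evaluation total: log|x| with log 0 = 0,
√|x|, and x/y = 1 when |y| < 10⁻¹² — standard symbolic-regression practice.
Features are min-max normalised to [0, 1] with training extremes (test
values clipped; constant columns map to 0) so operator scales are
comparable.

Fitness is |ρ_Spearman| with average ranks on ties; the absolute value is
used because a tree's sign is arbitrary (negating a useful expression is one
mutation away). Search: generation size 1,000 for 10 generations; grow-style
initialisation with leaf probability d/(max_depth+1) at depth d and a forced
leaf at the bound; elitism (top 5% copied unchanged, which makes the best
fitness provably non-decreasing — asserted at run time); parents drawn with
linear-rank weights; subtree crossover (depth-violating children redrawn up
to 8 times, then the first parent passes through) and subtree mutation grown
to the remaining depth budget. Fitness values are cached by a canonical
expression key with commutative operands sorted — a pure speed optimisation
— and the returned top-3 are distinct under that key, so the output is never
three spellings of one formula. Expression strings round-trip through a
small infix parser with ordinary precedence.

## Classification and evaluation

The gradient-boosted classifier is deliberately delegated to XGBoost — it is
the one off-the-shelf stage, used with the fixed hyperparameters listed in
the README, single-threaded histogram trees for determinism under a seed.
Hyperparameter search is out of scope; a plain 3-fold stratified CV harness
(`cross_val_auc`) is provided for manual tuning. AUC is computed as the
Mann–Whitney rank statistic with ties counted ½ (verified against exhaustive
pair enumeration and scikit-learn). Importance is the split count
("weight"): how many times a feature is chosen as a split variable across
the ensemble — not gain. The false-negative profile uses a 0.5 probability
threshold (AUC itself needs none; 0.5 is the conventional default). The
learning curve refits at each grid point, which with deterministic boosting
equals truncating a longer fit.

## Pipeline reproducibility

A single global seed derives one sub-seed per stochastic stage
(cohort, split, GP, classifier) via `SeedSequence([seed, stage_id])`,
truncated below 2³¹, so any stage can be re-run alone with identical output.
All fitted objects are JSON (binning scheme, imputation plan, GP features),
all tables CSV; re-running a configuration reproduces the JSON artifacts
bit-identically. The persisted booster uses XGBoost's native format.

## Problem sizes

Default experiments use n = 10,000 patients with 30 feature columns (6
informative + 24 noise) — a deliberate desk-scale stand-in for a
44,854 × 129 database; the generator scales up by configuration. The
acceptance script's quantities (test AUC ≈ 0.90, prevalence ≈ 23%, five age
bins, GP fitness ≈ 0.55–0.59 vs best raw ≈ 0.40) are properties of this
synthetic design, not estimates of any clinical dataset.

## Limitations

* MCAR missingness and log-normal marginals are idealisations; passing tests
  show the pipeline's logic is correct under its assumptions, not that the
  classifier would reach the same AUC on real exam data.
* The GP explores a small operator set without constants or parsimony
  pressure; fitted expressions should be read as rank-correlates, not
  clinical indices.
* Split-count importance undervalues features used rarely but decisively;
  gain-based importance is intentionally not offered to keep the diagnostic
  comparable with the split-count definition.
* With five bins on ~78 distinct ages, ChiMerge cut points are sensitive to
  sampling noise near prevalence plateaus; the bin *count* is stable, the
  exact cuts are not.
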