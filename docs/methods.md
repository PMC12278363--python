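# Methods

This note documents the statistical procedures implemented in `pvsignal`,
the modelling assumptions behind them, the defaults and why they were
chosen, and what the bundled synthetic-data generator does and does not
emulate.

## Counting unit and deduplication

The unit of analysis is the **deduplicated case**, not the report version
and not the drug–report pair. A case (`caseid`) may be submitted in several
versions (`caseversion`, `primaryid`); deduplication keeps, per case, the
version with the greatest `(caseversion, primaryid)` in lexicographic
order — the latest-submission rule common in FAERS practice. The operation
is idempotent, and the read → dedup round trip is tested against the
generator's known surviving versions. Regulatory recipes that additionally
consult the FDA receipt date are not modelled; the version key is the only
ordering used.

Exposure means appearing in a case's DRUG table under a *suspect* role —
primary or secondary suspect (`PS`, `SS`) by default; concomitant and
interacting drugs are excluded. The role set is configurable.

A case whose reactions match two different event definitions participates
in both analyses independently by default; a `dual_flag_policy: drop`
switch removes dual-flagged cases instead. Neither behaviour is claimed to
be canonical — reporting conventions differ — so both are provided and the
run report records the counts.

## Disproportionality

For drug *D* and event group *E* over *N* deduplicated cases:

|            | target cases | all other AE cases |
|------------|--------------|--------------------|
| exposed    | a            | b                  |
| not exposed| c            | d                  |

ROR = ad/bc; the 95% CI is Woolf's, exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
The association test is the Pearson chi-square with 1 df (no continuity
correction by default; Yates available via config, since conventions vary),
and p-values are Bonferroni-adjusted with family size *m* = the number of
drugs actually tested for that event (drugs with a ≥ 1); *m* is recorded in
the run report because the choice of family is a genuine degree of freedom.

The screen is the conjunction a ≥ 3 **and** a > 100 **and** ROR₀₂₅ > 1
**and** adjusted p < 0.01, with strict inequalities on the last three
("more than", "exceeding", "below"); a config switch relaxes the count gate
to ≥. The denominator convention is "all other drugs": a case exposed to
several drugs contributes to the exposed cell of each of them.

**Zero cells.** The scalar `compute_ror` raises on any zero cell unless the
Haldane–Anscombe +0.5 correction is enabled; the bulk `analyze` path
instead reports NaN estimates for zero-cell drugs and flags them (they can
never be signals), so one sparse drug cannot abort a whole-corpus screen.

## Risk-factor models

The design matrix has one row per deduplicated case: outcome = the event
flag; covariates = sex (female reference; `male`, `missing`), age stratum
(<36 reference; 36–53, 53–66, 66–80, 80–120, `missing`) and one binary
indicator per candidate drug. Intervals are half-open [lo, hi) with the
last stratum closed at 120; ages outside [0, 120] are treated as missing.
Missing sex/age enter as explicit factor levels rather than dropping rows:
age is missing for ~30% of spontaneous reports, and deleting those cases
would change the analysed population.

**Selection.** Drugs are selected by L1-penalised logistic regression over
a geometric penalty grid descending from the smallest λ that zeroes every
coefficient (λ_max = max|xᵀ(y−ȳ)|/n) to λ_max·10⁻³ in 30 steps. The
penalty is chosen by K-fold (default 5) cross-validated deviance; the
default rule is the minimum mean deviance, with the one-standard-error rule
available (`lambda_rule: 1se`) — both λs are reported. Folds are assigned
by hashing case ids, and rows are sorted by case id before fitting, so the
selection is invariant to row order by construction. Binary drug indicators
share a scale, so predictors are not standardised by default (a switch
exists). Demographic covariates are penalised in the path fit but are
always carried into the final model regardless of shrinkage — only drugs
are subject to selection. The underlying solver is scikit-learn's
liblinear; it penalises the intercept, which is mitigated with a large
`intercept_scaling` (100), a standard device whose residual effect is
negligible at these sample sizes.

**Inference.** The final model is an unpenalised maximum-likelihood
logistic regression (statsmodels). Per covariate: OR = exp(β), 95% CI =
exp(β ± 1.96·se) from observed-information standard errors, Wald p-values,
significance at p < 0.01. Wald rather than profile-likelihood intervals
keeps the CI symmetric on the log-odds scale, matching how such ORs are
conventionally reported. Constant columns are dropped with a logged
warning. Quasi-separation is detected heuristically (|β| > 15 or se > 100)
and reported, never silently repaired; a Firth-style fallback is
deliberately not applied by default.

**Discrimination.** The AUC is computed by the Mann–Whitney rank
formulation with ties counted ½ — exactly the pairwise concordance
probability — and is tested against an exhaustive O(n²) pair-counting
oracle. Curve points come from scikit-learn's `roc_curve` at every distinct
threshold.

## Time to onset

Onset = event date − therapy start date, in days, per (case, suspect drug)
pair where both dates resolve to at least year+month precision.
Month-precision dates (FAERS `YYYYMM`) are imputed to the first of the
month and the record flagged `imputed`; year-only dates are excluded, as
are missing dates and negative differences, each counted by reason.
Event-group summaries first reduce to one record per case — the one with
the earliest therapy start — since a multi-drug case has no unique onset;
per-drug summaries keep all (case, drug) pairs. Quantiles use numpy's
linear-interpolation convention. Censoring-aware survival modelling is out
of scope: only medians, quartiles and the raw vectors (for violin plots)
are produced.

## The synthetic generator

`pvsignal.synthetic` emulates a spontaneous-reporting stream: case
demographics with female predominance (~66%), ages ≈ N(55, 18²) truncated
to [1, 119], FAERS-like per-field missingness (defaults: sex 10%, age 32%,
weight 70%, reporter occupation 6% — the magnitudes typical of
thyroid-dysfunction report cohorts), reporter occupations dominated by
physicians and consumers, multiple drugs per case with role codes, filler
drugs and reaction terms for non-event content, duplicate case versions at
a configurable rate (the superseded version has its age blanked so the
dedup rule is observable), `YYYYMMDD` dates with a configurable
month-precision rate, and therapy-to-onset days drawn from a log-normal
(default μ=3.7, σ=1.0, median ≈ 40 days; gamma and exponential available,
per-drug overrides supported).

The event model is logistic: a case is a target-event case with probability
expit(logit(p₀) + Σⱼ xⱼ·ln ORⱼ + male·ln OR_sex + ln OR_age-bin). Every
planted effect is therefore a *conditional* odds ratio — exactly the
estimand of the downstream multivariate logistic fit, which makes
parameter-recovery tests well-posed. Exposures are drawn independently per
drug per case; the marginal 2×2 odds ratio of the screen is consequently
close to, but (by non-collapsibility) not identical to, the planted
conditional OR when other effects are present.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real spontaneous-report data: correlated
co-prescription, confounding by indication, reporting and notoriety biases,
verbatim drug-name noise beyond case differences, country/reporter-region
structure, MedDRA hierarchy effects, and missingness that is informative
rather than completely at random.

The reference recovery benchmark (`standard_recovery_config`) fixes the
study conditions for the package's recovery checks: 50,000 cases, 10 drugs
with true OR 5 and 40 null drugs all at 2% exposure, baseline event
probability 0.10, male-vs-female OR 0.7, 5% duplicates, fixed seed. At this
size the planted drugs have expected a ≈ 370 target-event reports (clearing
the a > 100 gate) while null drugs sit near the gate with no statistical
support — the regime the screen is designed for.

## Determinism and numerics

All randomness derives from explicit integer seeds via numpy Generators;
identical config+seed reproduces byte-identical generator output and
byte-identical pipeline export directories (fixed column orders, stable
mergesorts, fixed float formatting). Volcano ordinates clamp p at the
smallest positive normal double before −log₁₀. The chi-square uses
`scipy.stats.chi2_contingency` in the scalar path and the closed-form
Pearson statistic in the vectorised path; their agreement is tested to
1e-10. Simulation-based checks in the test suite use the sizes quoted above
(2,000 replicates for calibration/FWER, 200 replicate fits for coverage,
50,000 cases for recovery), chosen to keep Monte-Carlo error well inside
the asserted bands.

## Known limitations

* The dedup rule is version-based only; recipes keyed to FDA receipt dates
  will differ on real extracts.
* Bonferroni family size depends on the drug universe present in the data;
  comparisons across corpora need a fixed family.
* The LASSO path solves each grid point independently (liblinear); very
  small penalties on near-separated data may stop at the iteration cap,
  which is logged.
* Onset records ignore censoring and duplicate event dates within a case;
  medians on heavily month-imputed data inherit up to ±15 days of date
  noise.
* Legacy (pre-2012Q4) FAERS column layouts are not auto-detected; readers
  expect the modern column names.
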