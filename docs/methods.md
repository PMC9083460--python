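# Methods

`dietmsm` implements a longitudinal diet-quality/survival analysis for
cancer-survivorship cohorts with up to three annual dietary assessments:
six a priori diet-quality indices are scored per subject-visit, the
5-level (quintile) time-updated exposure is weighted by stabilized inverse
probabilities of treatment and censoring, and marginal structural Cox
models estimate its effect on all-cause and cancer-specific mortality.
Because real cohorts of this kind are rarely shareable, the package also
contains a synthetic-cohort generator with a fully known causal structure,
so that every stage — scoring, weighting, model fitting — is verifiable
against ground truth.

## Diet-quality indices

All six indices consume one subject-visit intake row (food-group
servings/day, nutrient amounts, percent energy by macronutrient and
source, alcohol g/day, total energy).

**AHEI-2010** (0–110). Eleven components scored 0–10 against absolute
intake thresholds with linear interpolation between the floor and the
ceiling. The component table (`dietmsm.scores.AHEI_COMPONENTS`) is a plain
editable dict because FFQ derivations differ between studies; the shipped
defaults reward vegetables (ceiling 5 servings/d), fruit (4), whole grains
(3), nuts/legumes (1), EPA+DHA (250 mg/d) and PUFA (10% energy), and
penalize sugar-sweetened beverages, red/processed meat, trans fat, and
sodium (fixed mg cut-points 1112/3337 standing in for population decile
bounds). Alcohol gets full credit in a moderate window of 5–15 g/day,
2.5 points for abstainers, and zero at or above 35 g/day, with linear
interpolation between segments; the window is unisex because intake rows
carry no sex.

**aMED** (0–9). Nine median-split components computed within visit:
+1 for intake above the visit-specific cohort median of vegetables,
legumes, fruits, nuts, cereals, fish, and the MUFA:SFA ratio; +1 for
red/processed meat below the median; +1 for alcohol in [5, 15] g/day.

**DASH** (8–40). Eight components each contributing its within-visit
quintile rank (1–5), reversed for sodium, red/processed meat, and
sugar-sweetened beverages. The floor is 8 (eight components × rank 1),
which is what the rank-sum construction yields even though the range is
often quoted as "0–40".

**Low-carbohydrate indices** (0–30; total, animal, plant). Eleven
within-visit quantile strata scored 0–10, ascending in percent energy from
fat and from protein (the variant selects total, animal-source, or
vegetable-source fields) and descending in percent energy from
carbohydrate. Eleven strata scored 0–10 is the construction that actually
produces the 0–30 range (ten deciles would top out at 27).

**Quantile machinery.** All rank-based scores and the exposure quintiles
use minimum-rank binning: `bin = ceil(rank_min · B / n)`. Ties therefore
land in the lower bin as a group, deterministically; a constant vector is
a degenerate-distribution error. Quintiles, medians and strata are
computed within visit (the ranking the transition summaries track);
baseline-anchored binning can be had by scoring each visit against the
baseline cohort.

**Trend variable.** For the linear-trend test every subject-visit receives
the median score of its quintile at that visit, modeled downstream as a
continuous time-updated covariate.

## Cohort assembly

Eligibility filters run sequentially (ineligible tumor site; missing
baseline-FFQ pages; >70 blank responses on any FFQ; missing baseline
covariates; >5,000 kcal on any FFQ), and the exclusion ledger records the
count removed by each rule in application order, so a subject failing two
rules is counted once. Tongue tumors collapse into the oral-cavity site
class and hypopharynx into larynx before modeling (the hypopharynx stratum
is too sparse to support positivity on its own).

Follow-up time is days since diagnosis. Visits open intervals; the last
interval closes at the administrative horizon (3 years after the baseline
visit) for fully observed subjects, or one median inter-visit gap after
the last attended visit for dropouts. Missing interior visit dates are
filled by adding/subtracting the cohort median inter-visit gap to the
nearest documented date. Deaths close the interval containing the death
date; subjects missing both follow-up assessments are censored at the end
of the first interval. Loss to follow-up is flagged separately from
administrative censoring because only the former is modeled by IPCW.

A subject with exactly one missing visit among three (and two observed)
has that visit's index scores, caloric intake, and — when missing — BMI
imputed as the mean of the two observed values (trajectory mean); the
operation is idempotent and flags imputed rows. Subjects with two or more
missing visits are handled by the censoring rule, not imputation.

Cancer-specific analyses recode non-cancer deaths as censoring at the
death time — a cause-specific hazard interpretation; the time structure is
identical to the all-cause table.

## Weights

For subject *i* at visit *t* the stabilized treatment weight is

    sw_it^IPTW = ∏_{k≤t} P(A_k = a_ik | A_{k−1}, V) / P(A_k = a_ik | A_{k−1}, V, L_k)

with A the exposure quintile, V the baseline covariates, and L the
time-varying confounders (BMI and caloric intake). Both the numerator and
denominator are pooled proportional-odds models (multinomial available by
config); the denominator adds each time-varying confounder through a
restricted cubic spline with 3 knots at its 10th/50th/90th percentiles.
No exposure history exists at the first visit, so separate lag-free models
are fit there. The censoring weight is the analogous cumulative ratio of
predicted probabilities of remaining free of loss to follow-up (pooled
logistic models); administrative censoring is non-informative by
construction and is not modeled. By default the denominator's time-varying
covariates are those measured at the visit opening the interval
(`censoring_L="lagged"` uses the previous visit's instead). The final
weight is the product, truncated by default at the 98th percentile of the
pooled weight distribution (rows at or above the cut-point are assigned
the cut-point; raw values are retained). Diagnostics summarize
min/max/mean/median per index and visit and flag means deviating from 1 by
more than 0.5.

Numerical notes: ordinal-model design matrices are standardized before
optimization (predictions are invariant); near-constant time-varying
covariates are skipped by the spline expansion; a zero denominator
probability raises a positivity error naming the row.

## Outcome models

All time-varying fits are Cox partial likelihoods on counting-process data
(`(start, stop]` rows with left truncation), Efron tie handling, and —
for weighted and primary fits — robust sandwich variance clustered by
subject. The marginal structural model carries the time-updated quintile
dummies (Q2–Q5 vs Q1), the index score measured at the previous encounter,
and baseline age, sex, HPV status, tumor site, stage, treatment modality,
comorbidity (ACE-27), education, smoking, baseline BMI and baseline
calories. The first interval has no previous encounter; its lag term is
filled with the cohort median of the current measure, a constant that is
absorbed without duplicating the exposure (filling with the subject's own
current score would be collinear with it). The unweighted fit is the same
model without weights, and the baseline-only fit is a conventional Cox
model on one row per subject with baseline exposure and covariates,
administratively right-censored at 3 years.

Dose-response is assessed four ways: a Wald test on the quintile-median
trend covariate; an SD-scaled linear term reported as HR per SD; an added
quadratic term whose Wald p is reported separately (the HR per SD comes
from the linear-only model); and a 5-knot restricted cubic spline of the
continuous score, with the curve referenced to the median score (HR there
is exactly 1) and pointwise 95% bands by the delta method on the robust
spline-coefficient covariance. Effect modification by baseline stage, HPV
status, or tumor site uses a likelihood-ratio statistic comparing weighted
partial likelihoods with and without score-by-modifier products; under
weighting this LRT is approximate, and it is reported as such, together
with stratum-specific HRs per SD (zero-event strata are dropped from the
stratum report with a warning). Adjusted survival curves come from
marginal standardization: the weighted Breslow baseline hazard of the
fitted MSM, averaged over the observed covariate distribution with the
exposure set to each quintile in turn (the lag term is set to that
quintile's mean observed lag). A sensitivity analysis re-runs weights and
MSM after censoring subjects with imputed records at the end of the first
interval.

## Synthetic cohorts

**Causal generator.** Discrete annual visits k = 1..3 at times 0, 1, 2
years; administrative horizon at 3 years. Baseline covariates are drawn to
match the margins of a head-and-neck-cancer survivorship cohort (age
N(61.1, 11.2); 24.8% female; smoking current/former/never
.363/.353/.284; 69.2% stage III–IV; site larynx-hypopharynx/oral
cavity/oropharynx .226/.364/.410; BMI N(27.7, 5.8) floored at 14; calories
LogNormal(log 2000, 0.3) for positivity). The exposure level A_k ∈ {1..5}
follows a proportional-odds model with linear predictor
α_AA·(A_{k−1}−3) + α_LA·z(L_k) over cut-points placed for uniform
quintiles at zero predictor; the confounder updates as
L_{k+1} = L_k + γ_AL·(A_k−3) + N(0,1); the per-interval event probability
is expit(logit(p₀) + β_A·(A_k−1) + α_LY·z(L_k)) and dropout is
expit(logit(q₀) + α_Lc·z(L_k)), with z the fixed (27.7, 5.8)
standardization. Deaths are placed uniformly within their interval so
event times are untied; cause is cancer with probability 74/93. Defaults:
α_AA=0.8, α_LA=0.6, γ_AL=0.4, α_LY=0.3, β_A=−0.2, p₀=0.06, q₀=0.08,
α_Lc=0.3. Identical configs produce identical tables. The true β_A and a
confounding flag are emitted with every cohort and never altered
downstream.

**What the generator does and does not emulate.** It reproduces the
statistical structure the estimator relies on — treatment-confounder
feedback, informative dropout, annual measurement, a rare outcome — but
not dietary measurement error, FFQ item correlation structure, seasonal
intake variation, or covariate-dependent visit timing. Passing tests
demonstrate that the weighting and fitting machinery is correct under its
assumed model, not that those assumptions hold in any real cohort.

**Recovery benchmark.** The benchmark configuration strengthens the
feedback (α_LA=1.2, γ_AL=2.0, α_LY=0.5, α_Lc=0.5, β_A=−0.2, n=5,000) so
the unweighted estimator's omitted-variable bias,
≈ α_LY·Cov(A, z)/Var(A) ≈ 0.15 per exposure step, is clearly detectable.
Over 200 replicates the weighted (MSM) estimate of the per-step log hazard
ratio is compared to the conditional truth; the tolerance (|bias| < 0.05)
absorbs three small, well-understood gaps between the estimand and β_A:
hazard-vs-odds scale at p₀ ≈ 0.06 (≈ 0.006), non-collapsibility of the
hazard ratio over the residual confounder (≈ 0.01), and Monte-Carlo error.
Two design points matter and are deliberate: the benchmark MSM includes
the lagged exposure level (stabilized weights preserve the dependence of
A_k on A_{k−1}, so omitting the lag leaves the A_{k−1}→L_k→event path
open), and the benchmark weights are untruncated — truncation trades
variance for bias toward the unweighted estimator, the right trade for a
small real cohort but a contaminant in a bias/coverage measurement at
n = 5,000. The pipeline default remains 98th-percentile truncation.

**Accounting fixture.** A 550-subject roster with disjoint exclusion
strata (45 ineligible site, 17 missing FFQ pages, 7 with >70 blank
responses, 7 missing a baseline covariate, 6 with >5,000 kcal among the
otherwise eligible) leaving 468 eligible subjects; their visit pattern
(78 baseline-only, 230 two-visit, 160 three-visit, of whom 25 are missing
visit-2 and 20 visit-3 values, 12 of those also missing BMI) yields
exactly 1,018 person-periods with 45 imputable records (4.4%), 93 deaths
(74 cancer). This is the fixture the exclusion, imputation, and
person-period accounting tests run against.

## Problem sizes and runtime

Tests use cohorts of 400–5,000 subjects. The stabilization check runs one
n=5,000 cohort; the recovery benchmark runs 200 replicates at n=5,000
(roughly 4 s each single-threaded). The acceptance script computes only
the deterministic structural targets and finishes in seconds.

## Known limitations

- The weighted LRT for interactions and the robust-variance pairing is
  approximate under weighting; bootstrap inference is out of scope.
- Competing risks are handled only as cause-specific hazards (no
  Fine–Gray subdistribution model).
- Quintile exposure coding discards within-quintile variation by design;
  the continuous and spline codings are provided alongside.
- The proportional-odds exposure model is an assumption; a multinomial
  family is available but the benchmark's generative model is
  proportional-odds, so misspecification robustness is not measured.
- Trajectory-mean imputation understates within-subject variance; the
  sensitivity re-run (censoring imputed subjects early) is the packaged
  guard, mirroring the primary/sensitivity comparison design.
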