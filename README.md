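# dietmsm

Diet-quality index scoring and marginal structural Cox models for
longitudinal survivorship cohorts.

Nutritional-epidemiology survival analyses usually enter diet as a single
baseline measurement, even though intake changes over a disease course and
time-varying covariates such as BMI and caloric intake both respond to past
diet and predict future diet and death. Conventional regression adjustment
for such covariates is biased in exactly this setting (treatment-confounder
feedback). `dietmsm` implements the standard remedy — marginal structural
Cox models estimated by stabilized inverse-probability weighting — as a
tested, end-to-end pipeline for cohorts with annual dietary assessments,
written for biostatisticians and epidemiologists working with head-and-neck
(or similar) cancer survivorship data.

The pipeline:

1. **Diet scores** — six a priori indices per subject-visit: AHEI-2010
   (absolute thresholds, 0–110), aMED (median splits, 0–9), DASH (quintile
   ranks, 8–40), and three low-carbohydrate indices (macronutrient quantile
   strata, 0–30; total/animal/plant), plus within-visit quintiles, a
   quintile-median trend covariate, lagged exposures, and quintile
   transition matrices across visits.
2. **Cohort assembly** — sequential eligibility filters with an exclusion
   ledger, follow-up timelines with administrative censoring 3 years after
   the baseline visit, trajectory-mean imputation of a single missing
   visit, and counting-process person-period records.
3. **Weights** — stabilized IPTW for the 5-level exposure via
   proportional-odds models (time-varying BMI and calories enter the
   denominator through 3-knot restricted cubic splines), stabilized IPCW
   for loss to follow-up, product weights truncated at the 98th percentile,
   and per-visit diagnostics. For subject *i* at visit *t*:

   ```
   sw_it = ∏(k≤t) P(A_k=a_ik | Ā_(k−1), V) / P(A_k=a_ik | Ā_(k−1), V, L̄_k)
         × ∏(k≤t) P(C_k=0 | Ā_(k−1), V) / P(C_k=0 | Ā_(k−1), V, L̄)
   ```

4. **Models** — the weighted (marginal structural) time-varying Cox model
   `λ_i(t) = λ₀(t) exp(β₁ A_i(t) + β₂ V_i + β₃ A_i(t−1))` with robust
   sandwich variance clustered by subject, the matching unweighted fit, and
   a conventional baseline-only Cox model; trend tests, SD-scaled linear and
   quadratic fits, 5-knot restricted-cubic-spline dose-response curves
   referenced to the median score, interaction likelihood-ratio tests, and
   marginally standardized survival curves per quintile.
5. **Synthetic cohorts** — a generator with a known conditional log hazard
   per exposure step and explicit treatment-confounder feedback, plus a
   550-subject accounting fixture, so every stage is testable without any
   restricted data. See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate a confounded cohort where the true effect of each one-quintile
step of diet quality is a log hazard ratio of −0.2, weight it, and compare
the weighted and unweighted estimates:

```python
from dietmsm import (SimulationConfig, simulate_person_periods,
                     WeightModelSpec, compute_stabilized_weights,
                     weight_diagnostics, fit_msm, fit_unweighted)

cfg = SimulationConfig(n_subjects=2000, seed=7, alpha_LA=1.2, gamma_AL=2.0,
                       alpha_LY=0.5, beta_A=-0.2)
pp, truth = simulate_person_periods(cfg)

spec = WeightModelSpec(lag_coding="quintile",
                       baseline_covariates=["age", "female"],
                       truncation_percentile=100.0)
w = compute_stabilized_weights(pp, spec)
print(weight_diagnostics(w).round(3).to_string(index=False))

msm = fit_msm(pp, w["sw"], covariates=["age", "female"],
              exposure="linear", lag_coding="quintile")
naive = fit_unweighted(pp, covariates=["age", "female"],
                       exposure="linear", lag_coding="quintile")
print(f"true log HR per step : {truth.beta_A_true:+.3f}")
print(f"MSM estimate         : {msm.params['A']:+.3f}")
print(f"unweighted estimate  : {naive.params['A']:+.3f}")
```

Output:

```
 interval   min    max  mean  median  misspecification_warning
        1 0.267 21.988 1.017   0.794                     False
        2 0.241 17.130 0.965   0.696                     False
        3 0.197 13.550 0.926   0.625                     False
true log HR per step : -0.200
MSM estimate         : -0.223
unweighted estimate  : -0.053
```

The stabilized-weight means sit near 1 at every visit (the standard
specification check). The weighted estimate recovers the −0.2 truth within
sampling error, while the unweighted time-varying Cox model — adjusted for
the same baseline covariates but not weighted — is biased three-quarters of
the way to the null by the confounder feedback.

## Command-line pipeline

Every stage is also a CLI subcommand reading/writing CSVs in a run
directory, so stages can be re-run in isolation:

```bash
dietmsm run --run-dir runs/demo --seed 42 --kind fixture
dietmsm report runs/demo
```

This generates the packaged 550-subject fixture, applies the five
eligibility filters (ledger: 45/17/7/7/6 removed, 468 remaining), scores
all six indices, imputes the 45 single-missing-visit records (4.4% of the
1,018 person-periods), computes weights per index, fits all three model
classes for both mortality outcomes, and renders a text report with weight
diagnostics shaped like a per-index/per-visit summary table plus quintile
hazard ratios, trend/quadratic p-values, and HR-per-SD columns. A YAML
config (`--config`) round-trips the full `PipelineConfig`; identical
config and seed reproduce every output byte-for-byte.

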