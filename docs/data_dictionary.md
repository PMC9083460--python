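# CSV column dictionary

All tables are plain CSV, ISO-8601 dates, empty fields for missing values.

## baseline.csv — one row per subject

| column | type | notes |
|---|---|---|
| subject_id | str | unique key across all tables |
| age | years | |
| sex | male / female | |
| smoking | never / current / former | |
| education | `<=HS` / `>HS` | highest attained |
| hpv | negative / positive / unknown-equivocal | |
| stage | `0-II` / `III-IV` | tumor stage |
| ace27 | none / mild / moderate / severe | comorbidity index |
| treatment | 6-level modality | surgery, surgery+adjuvant, radiation, chemoradiation, chemotherapy, palliative-unknown |
| site / site_raw | str | raw anatomical site; `tongue` collapses into `oral cavity`, `hypopharynx` into `larynx-hypopharynx` before modeling |
| ffq_pages_missing | bool | baseline FFQ had whole pages missing (exclusion rule 2) |
| bmi0, kcal0 | kg/m², kcal/day | baseline values (derived from visit 0 when absent) |
| diagnosis_date | date | survival time origin |

## visits.csv — one row per subject-visit (visit_index 0/1/2)

Intake fields (servings/day unless noted): `vegetables`, `fruit`,
`whole_grains`, `nuts`, `legumes`, `nuts_legumes` (= nuts + legumes),
`red_processed_meat`, `fish`, `ssb` (sugar-sweetened beverages),
`lowfat_dairy`, `cereal`; `alcohol_g` (g/day), `sodium_mg` (mg/day),
`epa_dha_mg` (mg/day); percent-energy fractions in [0, 1]:
`pct_energy_carb`, `pct_energy_protein_total/animal/veg`,
`pct_energy_fat_total/animal/veg`, `pct_energy_pufa`, `pct_energy_trans`;
`mufa_sfa_ratio` (unitless); `energy_kcal` (kcal/day); `bmi` (kg/m²);
`visit_date`; `ffq_blank_count` (blank responses on that visit's FFQ).

A row present with blank intake fields means the subject was tracked but
the FFQ is missing at that visit (imputation candidate); an absent row
means loss to follow-up.

## outcomes.csv — one row per subject

`subject_id`, `death_date` (empty if alive), `cause` (`cancer` / `other` /
empty), `last_contact_date`.

## score_panel.csv — one row per subject-visit

`subject_id`, `visit_index`, the six scores (`ahei2010`, `amed`, `dash`,
`lc_total`, `lc_animal`, `lc_plant`), `energy_kcal`, `bmi`,
`imputed_flag`, and per index: `<index>_quintile` (1–5, within-visit),
`<index>_trend` (median score of the subject's quintile at that visit),
`<index>_lag_score`, `<index>_lag_quintile` (previous visit; empty at
visit 0), plus `visit_date`.

## person_periods_<index>.csv — one row per subject-interval

| column | notes |
|---|---|
| subject_id, interval (1–3), visit_index | keys |
| start, stop | days since diagnosis, `(start, stop]` counting-process form |
| event_allcause, event_cancer | at most one event per subject, on its last row |
| censor_ltfu | 1 on the final row of subjects lost to follow-up (administrative censoring is 0) |
| A | exposure quintile at the interval-opening visit |
| score, trend, lag_score, lag_quintile | index score codings |
| bmi, energy_kcal | time-varying confounders at the interval-opening visit |
| baseline covariates | as in baseline.csv (site collapsed) |
| imputed_flag | interval uses imputed values |

## weights_<index>.csv — one row per person-period

`index`, `subject_id`, `interval`, `sw_iptw`, `sw_ipcw`, `sw_raw`
(untruncated product), `sw` (truncated), `truncated` (bool).

## Result tables

`exclusion_ledger.csv`: `rule`, `n_excluded` in application order plus a
`remaining` row. `weight_diagnostics.csv`: per (`index`, `interval`)
min/max/mean/median of `sw` and a `misspecification_warning` flag.
`results_time_varying.csv`: per (`index`, `outcome`, `model` ∈ {msm,
unweighted}) quintile HRs with 95% CIs (`hr_q2..hr_q5`), `p_trend`,
`p_q5_q1`, `hr_continuous` (per SD) with CI, `p_quadratic`, `n_events`,
`n_person_periods`. `results_baseline.csv`: the baseline-only Cox
analogue. `dose_response_<index>_<outcome>.csv`: `score`, `HR`, `HR_lo`,
`HR_hi` relative to the median score. `survival_curves_<index>_<outcome>.csv`:
standardized survival per quintile over event times.
`transitions_<index>.csv`: stacked 5×5 quintile transition counts per
adjacent visit pair.
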