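"""Synthetic cohort generation.

Three generators back the test surface of the pipeline:

``generate_exclusion_fixture``
    A 550-subject roster with disjoint strata flagged for each eligibility
    filter (ineligible tumor site, missing FFQ pages, excess blank FFQ
    responses, missing baseline covariates, implausible energy intake) plus
    an engineered longitudinal visit structure for the 468 eligible
    subjects (1,018 person-periods, 45 single-visit-missing records that
    the trajectory-mean imputation step must fill).

``generate_observational_cohort``
    A discrete-time longitudinal cohort with explicit treatment-confounder
    feedback: a time-varying confounder (BMI-like) influences both the
    5-level exposure (via a proportional-odds model) and the per-interval
    event and dropout hazards, while past exposure feeds back into the
    confounder.  The true conditional log-hazard per exposure step is
    recorded alongside the data, so weighting estimators can be benchmarked
    against a known target.

``generate_intake_profiles``
    Per subject-visit dietary intake tables carrying every field the six
    diet-quality indices consume, with an option to append constructed
    maximal/minimal-adherence rows for score-bound tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import InvalidConfigError

# Baseline covariate margins emulating a head-and-neck cancer survivorship
# cohort (age in years, BMI kg/m^2, energy kcal/day).
AGE_MEAN, AGE_SD = 61.1, 11.2
BMI_MEAN, BMI_SD = 27.7, 5.8
BMI_FLOOR = 14.0
KCAL_LOG_MEAN, KCAL_LOG_SD = np.log(2000.0), 0.3
P_FEMALE = 0.248
SMOKING_LEVELS = ("current", "former", "never")
SMOKING_P = (0.363, 0.353, 0.284)
P_ADVANCED_STAGE = 0.692
SITE_LEVELS = ("larynx-hypopharynx", "oral cavity", "oropharynx")
SITE_P = (0.226, 0.364, 0.410)
P_LOW_EDUCATION = 0.342
HPV_LEVELS = ("negative", "positive", "unknown-equivocal")
HPV_P = (0.327, 0.164, 0.509)
ACE27_LEVELS = ("none", "mild", "moderate", "severe")
ACE27_P = (0.265, 0.485, 0.179, 0.071)
TREATMENT_LEVELS = (
    "surgery",
    "surgery+adjuvant",
    "radiation",
    "chemoradiation",
    "chemotherapy",
    "palliative-unknown",
)
TREATMENT_P = (0.25, 0.30, 0.10, 0.25, 0.05, 0.05)
CANCER_DEATH_FRACTION = 74.0 / 93.0

DAYS_PER_YEAR = 365.25
VISIT_GAP_DAYS = 365

#: intake columns emitted by the intake-profile generator (servings/day
#: unless suffixed otherwise; percent-energy fields are kcal fractions).
INTAKE_COLUMNS = [
    "vegetables",
    "fruit",
    "whole_grains",
    "nuts",
    "legumes",
    "nuts_legumes",
    "red_processed_meat",
    "fish",
    "ssb",
    "lowfat_dairy",
    "cereal",
    "alcohol_g",
    "sodium_mg",
    "epa_dha_mg",
    "pct_energy_carb",
    "pct_energy_protein_total",
    "pct_energy_protein_animal",
    "pct_energy_protein_veg",
    "pct_energy_fat_total",
    "pct_energy_fat_animal",
    "pct_energy_fat_veg",
    "pct_energy_pufa",
    "pct_energy_trans",
    "mufa_sfa_ratio",
    "energy_kcal",
    "bmi",
]


@dataclass(frozen=True)
class TrueParameterRecord:
    """Ground truth emitted with every generated cohort; never altered downstream."""

    beta_A_true: float
    confounded: bool


@dataclass
class SimulationConfig:
    """Parameters of the longitudinal data-generating process.

    The exposure is a 5-level ordinal variable drawn each visit from a
    proportional-odds model; the confounder update and the event/dropout
    hazards are as documented in the methods note.  ``beta_A`` is the true
    conditional log-hazard per one-level exposure step.
    """

    n_subjects: int = 1000
    n_visits: int = 3
    seed: int = 0
    beta_A: float = -0.2
    alpha_AA: float = 0.8
    alpha_LA: float = 0.6
    gamma_AL: float = 0.4
    alpha_LY: float = 0.3
    base_event_prob: float = 0.06
    dropout_prob: float = 0.08
    alpha_Lc: float = 0.3
    cancer_death_fraction: float = CANCER_DEATH_FRACTION

    def validate(self) -> None:
        for name in ("base_event_prob", "dropout_prob", "cancer_death_fraction"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise InvalidConfigError(f"{name}={p} must lie in (0, 1)")
        if self.n_visits < 2:
            raise InvalidConfigError("n_visits must be >= 2")
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be positive")

    @property
    def true_params(self) -> TrueParameterRecord:
        return TrueParameterRecord(
            beta_A_true=self.beta_A,
            confounded=(self.alpha_LA != 0.0 and self.alpha_LY != 0.0),
        )


def _draw_baseline_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(AGE_MEAN, AGE_SD, n).round(1),
            "sex": np.where(rng.random(n) < P_FEMALE, "female", "male"),
            "smoking": rng.choice(SMOKING_LEVELS, n, p=SMOKING_P),
            "education": np.where(
                rng.random(n) < P_LOW_EDUCATION, "<=HS", ">HS"
            ),
            "hpv": rng.choice(HPV_LEVELS, n, p=HPV_P),
            "stage": np.where(rng.random(n) < P_ADVANCED_STAGE, "III-IV", "0-II"),
            "ace27": rng.choice(ACE27_LEVELS, n, p=ACE27_P),
            "treatment": rng.choice(TREATMENT_LEVELS, n, p=TREATMENT_P),
            "site": rng.choice(SITE_LEVELS, n, p=SITE_P),
        }
    )


def _zscore_bmi(bmi: np.ndarray) -> np.ndarray:
    return (bmi - BMI_MEAN) / BMI_SD


def _simulate_core(config: SimulationConfig) -> dict:
    """Run the discrete-time simulation; return per-visit arrays.

    Each visit k (1-based) happens at time k-1 (years).  Interval k spans
    (k-1, k].  Within interval k a subject may die (uniform time within the
    interval) or drop out (censored at the interval end); survivors attend
    visit k+1.  The administrative horizon is ``n_visits`` years.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, K = config.n_subjects, config.n_visits

    baseline = _draw_baseline_covariates(rng, n)
    bmi = np.clip(rng.normal(BMI_MEAN, BMI_SD, n), BMI_FLOOR, None)
    kcal = rng.lognormal(KCAL_LOG_MEAN, KCAL_LOG_SD, n)

    cuts = logit(np.array([0.2, 0.4, 0.6, 0.8]))
    lp_event0 = logit(config.base_event_prob)
    lp_drop0 = logit(config.dropout_prob)

    active = np.ones(n, dtype=bool)
    a_prev = np.full(n, 3, dtype=int)  # reference level for the first visit
    event_time = np.full(n, np.nan)
    end_time = np.full(n, float(K))
    ltfu = np.zeros(n, dtype=bool)
    died = np.zeros(n, dtype=bool)

    rows = []
    for k in range(1, K + 1):
        z = _zscore_bmi(bmi)
        eta = config.alpha_AA * (a_prev - 3) + config.alpha_LA * z
        if k == 1:
            eta = config.alpha_LA * z  # no exposure history at the first visit
        p_le = expit(cuts[None, :] - eta[:, None])
        a = 1 + (rng.random(n)[:, None] > p_le).sum(axis=1)

        p_event = expit(lp_event0 + config.beta_A * (a - 1) + config.alpha_LY * z)
        ev = rng.random(n) < p_event
        frac = rng.random(n)
        p_drop = expit(lp_drop0 + config.alpha_Lc * z)
        dr = (~ev) & (rng.random(n) < p_drop)

        idx = np.flatnonzero(active)
        rows.append(
            pd.DataFrame(
                {
                    "subject": idx,
                    "visit": k,
                    "A": a[idx],
                    "A_lag": np.where(k == 1, 0, a_prev[idx]),
                    "bmi": bmi[idx],
                    "kcal": kcal[idx],
                    "event": (ev[idx] & active[idx]).astype(int),
                    "dropout": (dr[idx] & active[idx]).astype(int),
                    "event_frac": frac[idx],
                }
            )
        )

        new_event = active & ev
        event_time[new_event] = (k - 1) + frac[new_event]
        end_time[new_event] = event_time[new_event]
        died |= new_event
        new_drop = active & dr
        end_time[new_drop] = float(k)
        ltfu |= new_drop
        active = active & ~ev & ~dr

        bmi = np.clip(
            bmi + config.gamma_AL * (a - 3) + rng.normal(0.0, 1.0, n),
            BMI_FLOOR,
            None,
        )
        kcal = kcal * np.exp(rng.normal(0.0, 0.15, n))
        a_prev = a

    visits = pd.concat(rows, ignore_index=True)
    cancer = died & (rng.random(n) < config.cancer_death_fraction)
    return {
        "baseline": baseline,
        "visits": visits,
        "event_time": event_time,
        "end_time": end_time,
        "died": died,
        "cancer": cancer,
        "ltfu": ltfu,
        "rng": rng,
    }


def simulate_person_periods(config: SimulationConfig) -> tuple[pd.DataFrame, TrueParameterRecord]:
    """Generate a cohort directly in counting-process person-period form.

    One row per subject-interval with ``start``/``stop`` in years since the
    baseline visit, the exposure level ``A`` observed at the interval start,
    its lag, the time-varying confounders, baseline covariates, the event
    indicator, and the loss-to-follow-up indicator ``censor`` (1 on the last
    row of subjects who dropped out; administrative censoring is coded 0).
    """
    core = _simulate_core(config)
    v = core["visits"].copy()
    v["start"] = v["visit"] - 1.0
    stop = v["visit"].astype(float)
    stop = np.where(v["event"] == 1, v["start"] + v["event_frac"], stop)
    v["stop"] = stop
    base = core["baseline"].copy()
    base["subject"] = np.arange(len(base))
    base["female"] = (base["sex"] == "female").astype(int)
    pp = v.merge(base[["subject", "age", "female", "smoking", "stage", "site"]], on="subject")
    pp = pp.rename(
        columns={
            "subject": "subject_id",
            "visit": "interval",
            "kcal": "energy_kcal",
            "event": "event_allcause",
            "dropout": "censor_ltfu",
        }
    )
    pp["event_cancer"] = pp["event_allcause"] * pp["subject_id"].map(
        pd.Series(core["cancer"].astype(int))
    )
    # exposure doubles as the continuous score in the benchmark setting
    pp["score"] = pp["A"].astype(float)
    pp["lag_quintile"] = pp["A_lag"].where(pp["interval"] > 1).astype(float)
    pp["lag_score"] = pp["lag_quintile"]
    pp = pp.drop(columns=["event_frac"])
    return pp.sort_values(["subject_id", "interval"]).reset_index(drop=True), config.true_params


def generate_observational_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TrueParameterRecord]:
    """Generate (baseline, visits, outcomes) tables plus the ground truth.

    Dates are ISO-8601; the baseline visit coincides with an annual visit
    schedule anchored at the diagnosis date.
    """
    core = _simulate_core(config)
    n = config.n_subjects
    rng = core["rng"]

    ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    diagnosis = pd.Timestamp("2010-01-01") + pd.to_timedelta(
        rng.integers(0, 1500, n), unit="D"
    )

    baseline = core["baseline"].copy()
    baseline.insert(0, "subject_id", ids)
    first_visit = core["visits"].query("visit == 1").set_index("subject")
    baseline["bmi0"] = first_visit["bmi"].reindex(range(n)).round(2).values
    baseline["kcal0"] = first_visit["kcal"].reindex(range(n)).round(0).values
    baseline["diagnosis_date"] = diagnosis.strftime("%Y-%m-%d")

    v = core["visits"].copy()
    v["subject_id"] = ids[v["subject"].values]
    offsets = pd.to_timedelta(
        ((v["visit"] - 1) * VISIT_GAP_DAYS).to_numpy(), unit="D"
    )
    v["visit_date"] = (
        pd.DatetimeIndex(diagnosis.values[v["subject"].values]) + offsets
    ).strftime("%Y-%m-%d")
    visits = v[
        ["subject_id", "visit", "visit_date", "A", "A_lag", "bmi", "kcal"]
    ].rename(columns={"visit": "visit_index", "kcal": "energy_kcal"})
    visits["visit_index"] -= 1  # visits indexed 0/1/2 in the table form
    visits["bmi"] = visits["bmi"].round(2)
    visits["energy_kcal"] = visits["energy_kcal"].round(0)

    death_days = np.round(core["event_time"] * DAYS_PER_YEAR)
    end_days = np.round(core["end_time"] * DAYS_PER_YEAR)
    death_date = np.where(
        core["died"],
        (diagnosis + pd.to_timedelta(np.nan_to_num(death_days), unit="D")).strftime(
            "%Y-%m-%d"
        ),
        "",
    )
    outcomes = pd.DataFrame(
        {
            "subject_id": ids,
            "death_date": death_date,
            "cause": np.select(
                [core["cancer"], core["died"]], ["cancer", "other"], default=""
            ),
            "last_contact_date": (
                diagnosis + pd.to_timedelta(end_days, unit="D")
            ).strftime("%Y-%m-%d"),
        }
    )
    return baseline, visits, outcomes, config.true_params


# ---------------------------------------------------------------------------
# dietary intake profiles
# ---------------------------------------------------------------------------

def _draw_intake(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random but nutritionally plausible intake rows."""
    nuts = rng.gamma(1.5, 0.3, n)
    legumes = rng.gamma(1.5, 0.3, n)
    macro = rng.dirichlet(np.array([0.50, 0.17, 0.33]) * 150.0, n)
    carb, protein, fat = macro[:, 0], macro[:, 1], macro[:, 2]
    prot_animal_frac = rng.beta(6, 3, n)
    fat_animal_frac = rng.beta(5, 4, n)
    pufa_frac = rng.beta(4, 8, n)
    alcohol = np.where(
        rng.random(n) < 0.35, 0.0, rng.lognormal(np.log(10.0), 0.8, n)
    )
    df = pd.DataFrame(
        {
            "vegetables": rng.gamma(4.0, 0.5, n),
            "fruit": rng.gamma(3.0, 0.5, n),
            "whole_grains": rng.gamma(2.0, 0.5, n),
            "nuts": nuts,
            "legumes": legumes,
            "nuts_legumes": nuts + legumes,
            "red_processed_meat": rng.gamma(2.0, 0.4, n),
            "fish": rng.gamma(1.5, 0.25, n),
            "ssb": rng.gamma(1.2, 0.4, n),
            "lowfat_dairy": rng.gamma(2.0, 0.5, n),
            "cereal": rng.gamma(2.0, 0.5, n),
            "alcohol_g": alcohol,
            "sodium_mg": np.clip(rng.normal(3000.0, 800.0, n), 500.0, None),
            "epa_dha_mg": rng.lognormal(np.log(120.0), 0.7, n),
            "pct_energy_carb": carb,
            "pct_energy_protein_total": protein,
            "pct_energy_protein_animal": protein * prot_animal_frac,
            "pct_energy_protein_veg": protein * (1.0 - prot_animal_frac),
            "pct_energy_fat_total": fat,
            "pct_energy_fat_animal": fat * fat_animal_frac,
            "pct_energy_fat_veg": fat * (1.0 - fat_animal_frac),
            "pct_energy_pufa": fat * pufa_frac,
            "pct_energy_trans": fat * rng.beta(2, 40, n),
            "mufa_sfa_ratio": rng.lognormal(np.log(1.1), 0.25, n),
            "energy_kcal": rng.lognormal(KCAL_LOG_MEAN, KCAL_LOG_SD, n),
            "bmi": np.clip(rng.normal(BMI_MEAN, BMI_SD, n), BMI_FLOOR, None),
        }
    )
    return df


def _extreme_rows() -> pd.DataFrame:
    """Constructed maximal- and minimal-adherence profiles.

    The 'best' row is designed to sit beyond every AHEI-2010 ideal
    threshold, above any plausible cohort median/quintile/stratum boundary
    on rewarded rank-based components, and below it on penalized ones; the
    'worst' row is the mirror image.
    """
    best = {
        "vegetables": 12.0,
        "fruit": 10.0,
        "whole_grains": 10.0,
        "nuts": 6.0,
        "legumes": 6.0,
        "nuts_legumes": 12.0,
        "red_processed_meat": 0.0,
        "fish": 6.0,
        "ssb": 0.0,
        "lowfat_dairy": 8.0,
        "cereal": 10.0,
        "alcohol_g": 10.0,
        "sodium_mg": 200.0,
        "epa_dha_mg": 800.0,
        "pct_energy_carb": 0.12,
        "pct_energy_protein_total": 0.30,
        "pct_energy_protein_animal": 0.05,
        "pct_energy_protein_veg": 0.25,
        "pct_energy_fat_total": 0.58,
        "pct_energy_fat_animal": 0.08,
        "pct_energy_fat_veg": 0.50,
        "pct_energy_pufa": 0.12,
        "pct_energy_trans": 0.0,
        "mufa_sfa_ratio": 5.0,
        "energy_kcal": 2000.0,
        "bmi": 25.0,
    }
    worst = {
        "vegetables": 0.0,
        "fruit": 0.0,
        "whole_grains": 0.0,
        "nuts": 0.0,
        "legumes": 0.0,
        "nuts_legumes": 0.0,
        "red_processed_meat": 4.0,
        "fish": 0.0,
        "ssb": 4.0,
        "lowfat_dairy": 0.0,
        "cereal": 0.0,
        "alcohol_g": 60.0,
        "sodium_mg": 7000.0,
        "epa_dha_mg": 0.0,
        "pct_energy_carb": 0.80,
        "pct_energy_protein_total": 0.06,
        "pct_energy_protein_animal": 0.05,
        "pct_energy_protein_veg": 0.01,
        "pct_energy_fat_total": 0.14,
        "pct_energy_fat_animal": 0.12,
        "pct_energy_fat_veg": 0.02,
        "pct_energy_pufa": 0.01,
        "pct_energy_trans": 0.06,
        "mufa_sfa_ratio": 0.2,
        "energy_kcal": 2000.0,
        "bmi": 25.0,
    }
    return pd.DataFrame([best, worst])


def generate_intake_profiles(
    n: int, seed: int, n_visits: int = 3, include_extreme: bool = False
) -> pd.DataFrame:
    """Visit-level intake table with all fields every diet index consumes.

    With ``include_extreme`` two constructed subjects ('BEST', 'WORST') are
    appended whose rows encode maximal/minimal adherence for every index at
    every visit.
    """
    if n < 10:
        raise InvalidConfigError("generate_intake_profiles requires n >= 10")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_visits):
        df = _draw_intake(rng, n)
        df.insert(0, "subject_id", [f"S{i + 1:05d}" for i in range(n)])
        df.insert(1, "visit_index", k)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if include_extreme:
        extra = []
        for k in range(n_visits):
            ex = _extreme_rows()
            ex.insert(0, "subject_id", ["BEST", "WORST"])
            ex.insert(1, "visit_index", k)
            extra.append(ex)
        out = pd.concat([out] + extra, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# exclusion / longitudinal accounting fixture
# ---------------------------------------------------------------------------

ELIGIBLE_RAW_SITES = ("oral cavity", "tongue", "oropharynx", "larynx", "hypopharynx")
INELIGIBLE_RAW_SITES = ("nasopharynx", "salivary gland", "sinonasal", "esophagus")
# raw-site draw for eligible subjects; tongue folds into oral cavity and
# hypopharynx into larynx during covariate preparation
ELIGIBLE_SITE_P = (0.24, 0.123, 0.410, 0.206, 0.021)

FIXTURE_N_TOTAL = 550
FIXTURE_N_SITE = 45
FIXTURE_N_PAGES = 17
FIXTURE_N_BLANKS = 7
FIXTURE_N_COVARIATE = 7
FIXTURE_N_KCAL = 6
# longitudinal pattern of the 468 eligible subjects: person-period rows
# total 78*1 + 230*2 + 160*3 = 1018, with 45 single-missing-visit records
FIXTURE_N_BASELINE_ONLY = 78
FIXTURE_N_TWO_VISITS = 230
FIXTURE_N_THREE_VISITS = 160
FIXTURE_N_IMPUTE_V2 = 25
FIXTURE_N_IMPUTE_V3 = 20
FIXTURE_N_MISSING_BMI = 12
FIXTURE_DEATHS = (20, 35, 38)  # deaths placed in intervals 1/2/3
FIXTURE_N_CANCER_DEATHS = 74


def generate_exclusion_fixture(seed: int = 42) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """550-subject roster exercising every eligibility filter.

    Returns ``(baseline, visits, outcomes)``.  Exclusion strata are
    disjoint, so applying the filters sequentially removes exactly
    45/17/7/7/6 subjects and leaves 468.  The eligible subjects carry an
    engineered visit pattern: 78 with a baseline FFQ only, 230 followed for
    two visits, and 160 followed for all three — 45 of whom are missing a
    single follow-up FFQ (25 at visit 2, 20 at visit 3; 12 of the latter
    also missing the visit-3 BMI), i.e. exactly the records the
    trajectory-mean imputation rule covers.
    """
    rng = np.random.default_rng(seed)
    n = FIXTURE_N_TOTAL
    ids = np.array([f"F{i + 1:04d}" for i in range(n)])

    baseline = _draw_baseline_covariates(rng, n)
    baseline.insert(0, "subject_id", ids)
    baseline["site_raw"] = rng.choice(ELIGIBLE_RAW_SITES, n, p=ELIGIBLE_SITE_P)
    baseline["ffq_pages_missing"] = False
    diagnosis = pd.Timestamp("2009-06-01") + pd.to_timedelta(
        rng.integers(0, 1200, n), unit="D"
    )
    baseline["diagnosis_date"] = diagnosis.strftime("%Y-%m-%d")

    order = rng.permutation(n)
    cut = np.cumsum(
        [FIXTURE_N_SITE, FIXTURE_N_PAGES, FIXTURE_N_BLANKS, FIXTURE_N_COVARIATE, FIXTURE_N_KCAL]
    )
    grp_site = order[: cut[0]]
    grp_pages = order[cut[0] : cut[1]]
    grp_blanks = order[cut[1] : cut[2]]
    grp_cov = order[cut[2] : cut[3]]
    grp_kcal = order[cut[3] : cut[4]]
    eligible = order[cut[4] :]

    baseline.loc[grp_site, "site_raw"] = rng.choice(
        INELIGIBLE_RAW_SITES, FIXTURE_N_SITE
    )
    baseline.loc[grp_pages, "ffq_pages_missing"] = True
    cov_cols = ["education", "hpv", "ace27", "smoking"]
    for i, row in enumerate(grp_cov):
        baseline.loc[row, cov_cols[i % len(cov_cols)]] = np.nan

    # visit-pattern assignment for eligible subjects
    eligible = rng.permutation(eligible)
    g1 = eligible[:FIXTURE_N_BASELINE_ONLY]
    g2 = eligible[FIXTURE_N_BASELINE_ONLY : FIXTURE_N_BASELINE_ONLY + FIXTURE_N_TWO_VISITS]
    g3 = eligible[FIXTURE_N_BASELINE_ONLY + FIXTURE_N_TWO_VISITS :]
    imp_v2 = g3[:FIXTURE_N_IMPUTE_V2]
    imp_v3 = g3[FIXTURE_N_IMPUTE_V2 : FIXTURE_N_IMPUTE_V2 + FIXTURE_N_IMPUTE_V3]
    miss_bmi = imp_v3[:FIXTURE_N_MISSING_BMI]
    nonimputed_g3 = g3[FIXTURE_N_IMPUTE_V2 + FIXTURE_N_IMPUTE_V3 :]

    n_visits_by_row = np.full(n, 3, dtype=int)
    n_visits_by_row[g1] = 1
    n_visits_by_row[g2] = 2

    frames = []
    for k in range(3):
        present = np.flatnonzero(n_visits_by_row > k)
        df = _draw_intake(rng, len(present))
        df.insert(0, "subject_id", ids[present])
        df.insert(1, "visit_index", k)
        df["energy_kcal"] = np.clip(df["energy_kcal"], None, 4800.0)
        df["ffq_blank_count"] = rng.integers(0, 30, len(present))
        df["visit_date"] = (
            pd.to_datetime(diagnosis.values[present])
            + pd.to_timedelta(k * VISIT_GAP_DAYS, unit="D")
        ).strftime("%Y-%m-%d")
        frames.append(df)
    visits = pd.concat(frames, ignore_index=True)

    # flag strata that live in the visit table
    for i, row in enumerate(grp_blanks):
        vk = int(rng.integers(0, 3))
        mask = (visits["subject_id"] == ids[row]) & (visits["visit_index"] == vk)
        visits.loc[mask, "ffq_blank_count"] = int(rng.integers(71, 130))
    for row in grp_kcal:
        vk = int(rng.integers(0, 3))
        mask = (visits["subject_id"] == ids[row]) & (visits["visit_index"] == vk)
        visits.loc[mask, "energy_kcal"] = float(rng.uniform(5100.0, 6500.0))

    # single-missing-visit records: rows exist (subject tracked) but the
    # FFQ-derived fields are blank
    intake_like = [c for c in INTAKE_COLUMNS if c != "bmi"]
    m2 = visits["subject_id"].isin(ids[imp_v2]) & (visits["visit_index"] == 1)
    visits.loc[m2, intake_like] = np.nan
    m3 = visits["subject_id"].isin(ids[imp_v3]) & (visits["visit_index"] == 2)
    visits.loc[m3, intake_like] = np.nan
    mb = visits["subject_id"].isin(ids[miss_bmi]) & (visits["visit_index"] == 2)
    visits.loc[mb, "bmi"] = np.nan

    # deaths in the last attended interval of selected subjects
    death_rows, death_interval = [], []
    for grp, n_dead, k in zip((g1, g2, nonimputed_g3), FIXTURE_DEATHS, (1, 2, 3)):
        chosen = grp[: n_dead]
        death_rows.extend(chosen)
        death_interval.extend([k] * n_dead)
    death_rows = np.array(death_rows)
    death_interval = np.array(death_interval)
    n_dead_total = len(death_rows)
    cancer_flags = np.zeros(n_dead_total, dtype=bool)
    cancer_flags[rng.choice(n_dead_total, FIXTURE_N_CANCER_DEATHS, replace=False)] = True

    death_date = np.full(n, "", dtype=object)
    cause = np.full(n, "", dtype=object)
    death_day = (death_interval - 1) * VISIT_GAP_DAYS + np.floor(
        rng.uniform(30, VISIT_GAP_DAYS - 30, n_dead_total)
    )
    for j, row in enumerate(death_rows):
        death_date[row] = (
            diagnosis[row] + pd.Timedelta(days=int(death_day[j]))
        ).strftime("%Y-%m-%d")
        cause[row] = "cancer" if cancer_flags[j] else "other"

    last_day = np.where(
        n_visits_by_row == 3,
        round(3 * DAYS_PER_YEAR),
        n_visits_by_row * VISIT_GAP_DAYS,
    )
    last_contact = np.array(
        [
            (diagnosis[i] + pd.Timedelta(days=int(last_day[i]))).strftime("%Y-%m-%d")
            for i in range(n)
        ],
        dtype=object,
    )
    last_contact[death_rows] = death_date[death_rows]
    outcomes = pd.DataFrame(
        {
            "subject_id": ids,
            "death_date": death_date,
            "cause": cause,
            "last_contact_date": last_contact,
        }
    )
    return baseline, visits, outcomes
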