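"""Cohort assembly: eligibility filters, follow-up timeline, imputation,
and counting-process person-period records.

The longitudinal design has up to three annual study visits (indices 0/1/2)
starting at diagnosis.  Follow-up time is measured in days since diagnosis;
administrative censoring falls ``horizon_years`` after the baseline visit.
Subjects missing both follow-up dietary measurements are treated as lost to
follow-up at the end of the first interval; a single missing visit is
filled by trajectory-mean imputation before the timeline is built.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .scores import INDEX_NAMES

ELIGIBLE_SITES = {"oral cavity", "tongue", "oropharynx", "larynx", "hypopharynx"}
#: anatomical collapse applied before modeling: tongue counts as oral
#: cavity; the sparse hypopharynx stratum folds into larynx
SITE_COLLAPSE = {
    "tongue": "oral cavity",
    "hypopharynx": "larynx-hypopharynx",
    "larynx": "larynx-hypopharynx",
    "oral cavity": "oral cavity",
    "oropharynx": "oropharynx",
}
REQUIRED_BASELINE_COVARIATES = [
    "age",
    "sex",
    "smoking",
    "education",
    "hpv",
    "stage",
    "ace27",
    "treatment",
]
MAX_BLANK_RESPONSES = 70
MAX_PLAUSIBLE_KCAL = 5000.0
DAYS_PER_YEAR = 365.25

EXCLUSION_RULES = [
    "ineligible_site",
    "missing_ffq_pages",
    "excess_blank_responses",
    "missing_baseline_covariate",
    "implausible_energy",
]


def apply_exclusions(
    baseline: pd.DataFrame, visits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sequentially apply the five eligibility filters.

    Returns ``(baseline_kept, visits_kept, ledger)``; the ledger records
    per-rule removal counts in application order, so a subject failing
    several rules is counted only under the first.
    """
    if baseline["subject_id"].duplicated().any():
        raise DataIntegrityError("duplicate subject_id in baseline table")

    site_col = "site_raw" if "site_raw" in baseline.columns else "site"
    remaining = baseline.set_index("subject_id")
    counts = []

    bad_site = ~remaining[site_col].isin(ELIGIBLE_SITES)
    if site_col == "site":  # already-collapsed site labels are eligible
        bad_site = ~remaining[site_col].isin(
            set(SITE_COLLAPSE.values()) | ELIGIBLE_SITES
        )
    counts.append(int(bad_site.sum()))
    remaining = remaining.loc[~bad_site]

    pages = (
        remaining["ffq_pages_missing"].fillna(False).astype(bool)
        if "ffq_pages_missing" in remaining.columns
        else pd.Series(False, index=remaining.index)
    )
    counts.append(int(pages.sum()))
    remaining = remaining.loc[~pages]

    if "ffq_blank_count" in visits.columns:
        blanks = visits.groupby("subject_id")["ffq_blank_count"].max()
        blank_fail = blanks.reindex(remaining.index).fillna(0) > MAX_BLANK_RESPONSES
    else:
        blank_fail = pd.Series(False, index=remaining.index)
    counts.append(int(blank_fail.sum()))
    remaining = remaining.loc[~blank_fail]

    cov_cols = [c for c in REQUIRED_BASELINE_COVARIATES if c in remaining.columns]
    missing_cov = remaining[cov_cols].isna().any(axis=1)
    counts.append(int(missing_cov.sum()))
    remaining = remaining.loc[~missing_cov]

    kcal_max = visits.groupby("subject_id")["energy_kcal"].max()
    kcal_fail = kcal_max.reindex(remaining.index) > MAX_PLAUSIBLE_KCAL
    kcal_fail = kcal_fail.fillna(False)
    counts.append(int(kcal_fail.sum()))
    remaining = remaining.loc[~kcal_fail]

    ledger = pd.DataFrame({"rule": EXCLUSION_RULES, "n_excluded": counts})
    ledger.loc[len(ledger)] = ["remaining", len(remaining)]
    kept = baseline[baseline["subject_id"].isin(remaining.index)].reset_index(drop=True)
    visits_kept = visits[visits["subject_id"].isin(remaining.index)].reset_index(drop=True)
    return kept, visits_kept, ledger


def prepare_covariates(baseline: pd.DataFrame) -> pd.DataFrame:
    """Collapse anatomical sites and normalize covariate levels for modeling."""
    out = baseline.copy()
    col = "site_raw" if "site_raw" in out.columns else "site"
    out["site"] = out[col].map(lambda s: SITE_COLLAPSE.get(s, s))
    return out


def impute_trajectory_mean(
    score_visits: pd.DataFrame,
    value_cols=None,
    n_visits: int = 3,
) -> pd.DataFrame:
    """Fill a single missing visit with the mean of the two observed ones.

    Operates on a per-visit table carrying diet index scores, caloric
    intake, and BMI.  Only subjects with exactly one missing visit among
    ``n_visits`` (and rows present for all of them) are imputed; subjects
    with two or more missing visits are left for the censoring rule.  The
    operation is idempotent, and imputed rows are flagged.
    """
    value_cols = list(
        value_cols
        or [c for c in INDEX_NAMES + ["energy_kcal", "bmi"] if c in score_visits.columns]
    )
    out = score_visits.copy()
    if "imputed_flag" not in out.columns:
        out["imputed_flag"] = False
    key_cols = [c for c in value_cols if c != "bmi"]
    for sid, grp in out.groupby("subject_id"):
        if len(grp) != n_visits:
            continue
        missing = grp[key_cols].isna().all(axis=1)
        if int(missing.sum()) != 1:
            continue
        obs = grp.loc[~missing]
        tgt = grp.index[missing][0]
        for col in value_cols:
            if pd.isna(out.at[tgt, col]):
                out.at[tgt, col] = obs[col].mean()
        out.at[tgt, "imputed_flag"] = True
        # BMI occasionally missing on its own for imputed subjects
    for sid, grp in out.groupby("subject_id"):
        if "bmi" in out.columns:
            bmi_missing = grp["bmi"].isna()
            if bmi_missing.any() and (~grp["bmi"].isna()).sum() >= 2:
                fill = grp["bmi"].mean()
                for tgt in grp.index[bmi_missing]:
                    out.at[tgt, "bmi"] = fill
                    out.at[tgt, "imputed_flag"] = True
    return out


def _parse_dates(series) -> pd.Series:
    return pd.to_datetime(series, errors="coerce")


def build_timeline(
    baseline: pd.DataFrame,
    visits: pd.DataFrame,
    outcomes: pd.DataFrame,
    horizon_years: float = 3.0,
) -> pd.DataFrame:
    """Per-subject interval records with event and censoring placement.

    A visit is *usable* when its dietary values are present (possibly via
    imputation), marked by non-missing ``energy_kcal``.  Usable visits must
    be contiguous from baseline; follow-up stops at the first gap.  Interval
    k runs from visit k to visit k+1 (for the last usable visit: to the
    administrative horizon for fully observed subjects, otherwise one
    median inter-visit gap further, capped at the horizon).  Deaths before
    the interval end close the interval with an event; loss to follow-up is
    flagged ``censor_ltfu`` on the final interval.
    """
    base = baseline.set_index("subject_id")
    out = outcomes.set_index("subject_id")
    diagnosis = _parse_dates(base["diagnosis_date"])
    if diagnosis.isna().any():
        raise DataIntegrityError("missing diagnosis dates")
    death = _parse_dates(out["death_date"]) if "death_date" in out.columns else None

    v = visits.copy()
    v["visit_date"] = _parse_dates(v["visit_date"])
    v["day"] = (
        v["visit_date"].values - diagnosis.reindex(v["subject_id"]).values
    ) / np.timedelta64(1, "D")

    # cohort median inter-visit gap from documented adjacent dates
    gaps = []
    for _, grp in v.sort_values("visit_index").groupby("subject_id"):
        d = grp["day"].to_numpy()
        gaps.extend(np.diff(d[~np.isnan(d)]).tolist())
    median_gap = float(np.median(gaps)) if gaps else 365.0

    usable = v["energy_kcal"].notna()
    n_total_visits = int(v["visit_index"].max()) + 1

    rows = []
    for sid, grp in v.groupby("subject_id"):
        grp = grp.sort_values("visit_index")
        u = grp[usable.reindex(grp.index)]
        # contiguity from the baseline visit
        vis_idx = u["visit_index"].to_list()
        n_contig = 0
        for j, k in enumerate(vis_idx):
            if k == j:
                n_contig += 1
            else:
                break
        if n_contig == 0:
            continue
        u = u.iloc[:n_contig]
        days = u["day"].to_numpy(dtype=float)
        # fill missing visit dates from the nearest documented date
        for j in range(len(days)):
            if np.isnan(days[j]):
                if j > 0 and not np.isnan(days[j - 1]):
                    days[j] = days[j - 1] + median_gap
                else:
                    later = np.flatnonzero(~np.isnan(days[j:]))
                    if later.size:
                        days[j] = days[j + later[0]] - median_gap * later[0]
        if np.isnan(days).any():
            raise DataIntegrityError(f"subject {sid}: no documented visit dates")

        admin_end = days[0] + horizon_years * DAYS_PER_YEAR
        n_vis = len(days)
        bounds = list(days) + [
            admin_end
            if n_vis == n_total_visits
            else min(days[-1] + median_gap, admin_end)
        ]

        death_day = np.nan
        if death is not None and sid in death.index and pd.notna(death.loc[sid]):
            death_day = (death.loc[sid] - diagnosis.loc[sid]) / np.timedelta64(1, "D")
            if death_day <= 0:
                raise DataIntegrityError(f"subject {sid}: death before diagnosis")
        has_event = bool(np.isfinite(death_day) and death_day <= bounds[-1])
        cause = out.loc[sid, "cause"] if has_event and "cause" in out.columns else ""

        for k in range(1, n_vis + 1):
            start, stop = bounds[k - 1], bounds[k]
            ev = 0
            if has_event and death_day <= stop:
                stop, ev = float(death_day), 1
            if stop <= start:
                # death recorded on a visit date boundary: give the interval
                # a nominal positive length
                stop = start + 0.5
            rows.append(
                {
                    "subject_id": sid,
                    "interval": k,
                    "visit_index": k - 1,
                    "start": float(start),
                    "stop": float(stop),
                    "event_allcause": ev,
                    "event_cancer": int(ev == 1 and cause == "cancer"),
                    "censor_ltfu": 0,
                }
            )
            if ev:
                break
        else:
            # no event: flag loss to follow-up unless fully observed
            if n_vis < n_total_visits:
                rows[-1]["censor_ltfu"] = 1
    timeline = pd.DataFrame(rows)
    return timeline.sort_values(["subject_id", "interval"]).reset_index(drop=True)


def build_person_periods(
    timeline: pd.DataFrame,
    panel: pd.DataFrame,
    baseline: pd.DataFrame,
    index_name: str,
) -> pd.DataFrame:
    """Counting-process rows for one diet index.

    Joins the timeline with the score panel (exposure quintile, trend value,
    lagged score/quintile, time-varying BMI and calories) and baseline
    covariates.  Both all-cause and cancer-specific event indicators are
    carried; a cancer-specific analysis treats non-cancer deaths as
    censoring at the death time (cause-specific hazard interpretation).
    """
    cols = {
        index_name: "score",
        f"{index_name}_quintile": "A",
        f"{index_name}_trend": "trend",
        f"{index_name}_lag_score": "lag_score",
        f"{index_name}_lag_quintile": "lag_quintile",
    }
    needed = ["subject_id", "visit_index", "energy_kcal", "bmi"] + list(cols)
    if "imputed_flag" in panel.columns:
        needed.append("imputed_flag")
    sub = panel[needed].rename(columns=cols)
    pp = timeline.merge(sub, on=["subject_id", "visit_index"], how="left", validate="1:1")
    if pp["A"].isna().any():
        missing = pp.loc[pp["A"].isna(), "subject_id"].unique()[:5]
        raise DataIntegrityError(
            f"person-periods without exposure values, e.g. subjects {list(missing)}"
        )
    base = prepare_covariates(baseline)
    keep = ["subject_id", "age", "sex", "smoking", "education", "hpv", "stage",
            "ace27", "treatment", "site", "bmi0", "kcal0"]
    keep = [c for c in keep if c in base.columns]
    pp = pp.merge(base[keep], on="subject_id", how="left")
    if "imputed_flag" not in pp.columns:
        pp["imputed_flag"] = False
    pp["imputed_flag"] = pp["imputed_flag"].fillna(False).astype(bool)
    pp["index"] = index_name
    bad = pp["stop"] <= pp["start"]
    if bad.any():
        raise DataIntegrityError("non-positive interval lengths in person-periods")
    return pp
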