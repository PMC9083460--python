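"""Diet-quality index scoring, quintile machinery, and transition summaries.

Six a priori indices are computed per subject-visit:

* **AHEI-2010** — eleven components scored 0-10 against absolute intake
  thresholds with linear interpolation between the floor and ceiling
  (total range 0-110).
* **aMED** — nine median-split components (0-9); the alcohol component is a
  fixed moderate-intake window of 5-15 g/day.
* **DASH** — eight quintile-ranked components, each contributing its
  quintile rank 1-5 (rank reversed for sodium, red/processed meat, and
  sugar-sweetened beverages), so totals span 8-40.
* **Low-carbohydrate** (total, animal, plant) — eleven quantile strata
  (0-10 points each) ascending in percent energy from fat and protein and
  descending in percent energy from carbohydrate (0-30).

All quantile-based indices are ranked within visit; ties are assigned to
the lower bin deterministically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDistributionError,
    DegenerateMedianError,
    RankingError,
    ScoringError,
)

INDEX_NAMES = ["ahei2010", "amed", "dash", "lc_total", "lc_animal", "lc_plant"]

# ---------------------------------------------------------------------------
# AHEI-2010: absolute-threshold components
# ---------------------------------------------------------------------------

#: component -> (field, intake at score 0, intake at score 10).  When the
#: floor exceeds the ceiling the component is penalized (less is better).
#: Servings/day unless the field name says otherwise; the whole-grain
#: ceiling is a servings-based equivalent of the published gram threshold,
#: and sodium uses fixed mg cut-points standing in for the population
#: decile boundaries.  The table is deliberately a plain dict so deployments
#: with different FFQ derivations can edit it.
AHEI_COMPONENTS: dict[str, tuple[str, float, float]] = {
    "vegetables": ("vegetables", 0.0, 5.0),
    "fruit": ("fruit", 0.0, 4.0),
    "whole_grains": ("whole_grains", 0.0, 3.0),
    "ssb": ("ssb", 1.0, 0.0),
    "nuts_legumes": ("nuts_legumes", 0.0, 1.0),
    "red_processed_meat": ("red_processed_meat", 1.5, 0.0),
    "trans_fat": ("pct_energy_trans", 0.04, 0.005),
    "epa_dha": ("epa_dha_mg", 0.0, 250.0),
    "pufa": ("pct_energy_pufa", 0.02, 0.10),
    "sodium": ("sodium_mg", 3337.0, 1112.0),
}

#: AHEI-2010 alcohol component (g/day): full credit inside the moderate
#: window, 2.5 points for abstainers, zero at/above the heavy threshold.
AHEI_ALCOHOL = {"window": (5.0, 15.0), "heavy": 35.0, "nondrinker_score": 2.5}


def _linear_component(x: float, lo: float, hi: float) -> float:
    """Score 0-10 linearly between the floor (score 0) and ceiling (score 10)."""
    if lo == hi:
        raise ScoringError("degenerate component thresholds")
    frac = (x - lo) / (hi - lo)
    return 10.0 * float(np.clip(frac, 0.0, 1.0))


def _alcohol_component(x: float) -> float:
    lo, hi = AHEI_ALCOHOL["window"]
    heavy = AHEI_ALCOHOL["heavy"]
    base = AHEI_ALCOHOL["nondrinker_score"]
    if x == 0.0:
        return base
    if x < lo:
        return base + (10.0 - base) * x / lo
    if x <= hi:
        return 10.0
    if x >= heavy:
        return 0.0
    return 10.0 * (heavy - x) / (heavy - hi)


def score_ahei2010(profile) -> float:
    """AHEI-2010 total (0-110) for one intake profile (mapping or Series)."""
    total = 0.0
    for name, (field, lo, hi) in AHEI_COMPONENTS.items():
        try:
            x = profile[field]
        except (KeyError, IndexError) as exc:
            raise ScoringError(f"profile is missing field '{field}'") from exc
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise ScoringError(f"profile field '{field}' is missing (NaN)")
        total += _linear_component(float(x), lo, hi)
    try:
        alc = profile["alcohol_g"]
    except (KeyError, IndexError) as exc:
        raise ScoringError("profile is missing field 'alcohol_g'") from exc
    total += _alcohol_component(float(alc))
    return total


def score_ahei2010_table(df: pd.DataFrame) -> pd.Series:
    """Vectorized AHEI-2010 over a table of profiles; NaN rows score NaN."""
    fields = [f for f, _, _ in AHEI_COMPONENTS.values()] + ["alcohol_g"]
    missing = [f for f in fields if f not in df.columns]
    if missing:
        raise ScoringError(f"intake table is missing fields: {missing}")
    total = np.zeros(len(df))
    for _, (field, lo, hi) in AHEI_COMPONENTS.items():
        frac = (df[field].to_numpy(dtype=float) - lo) / (hi - lo)
        total += 10.0 * np.clip(frac, 0.0, 1.0)
    alc = df["alcohol_g"].to_numpy(dtype=float)
    lo, hi = AHEI_ALCOHOL["window"]
    heavy = AHEI_ALCOHOL["heavy"]
    base = AHEI_ALCOHOL["nondrinker_score"]
    with np.errstate(invalid="ignore"):
        decline = 10.0 * (heavy - alc) / (heavy - hi)
        alc_score = np.select(
            [alc == 0.0, alc < lo, alc <= hi, alc >= heavy],
            [base, base + (10.0 - base) * alc / lo, 10.0, 0.0],
            default=0.0,
        )
        alc_score = np.where((alc > hi) & (alc < heavy), decline, alc_score)
    total += alc_score
    nan_mask = df[fields].isna().any(axis=1)
    total = np.where(nan_mask, np.nan, total)
    return pd.Series(total, index=df.index, name="ahei2010")


# ---------------------------------------------------------------------------
# quantile machinery (ties to the lower bin)
# ---------------------------------------------------------------------------

def quantile_bins(values: pd.Series, n_bins: int) -> pd.Series:
    """Rank-based quantile bins 1..n_bins with ties assigned to the lower bin.

    Uses minimum ranks, so a tie group straddling a bin boundary lands
    entirely in the lower bin; bin occupancy can differ from n/n_bins by at
    most the tie-group size.  NaNs propagate.
    """
    v = pd.Series(values).astype(float)
    obs = v.dropna()
    if len(obs) < n_bins:
        raise RankingError(
            f"{len(obs)} subjects cannot be split into {n_bins} quantile groups"
        )
    ranks = obs.rank(method="min")
    bins = np.ceil(ranks * n_bins / len(obs)).astype(int)
    out = pd.Series(np.nan, index=v.index)
    out.loc[obs.index] = bins
    return out


def assign_quintiles(scores: pd.Series) -> pd.Series:
    """Visit-specific score quintiles 1-5 (ties to the lower quintile)."""
    obs = pd.Series(scores).dropna()
    if obs.nunique() <= 1:
        raise DegenerateDistributionError("constant score vector has no quintiles")
    return quantile_bins(scores, 5)


def trend_values(scores: pd.Series, quintiles: pd.Series) -> pd.Series:
    """Median score of each subject's quintile — the linear-trend covariate."""
    scores = pd.Series(scores).astype(float)
    medians = scores.groupby(quintiles).median()
    return quintiles.map(medians)


# ---------------------------------------------------------------------------
# aMED (median split), DASH (quintile ranks), low-carbohydrate (11 strata)
# ---------------------------------------------------------------------------

AMED_GOOD = ["vegetables", "legumes", "fruit", "nuts", "cereal", "fish", "mufa_sfa_ratio"]
AMED_BAD = ["red_processed_meat"]
AMED_ALCOHOL_WINDOW = (5.0, 15.0)


def score_amed(profiles: pd.DataFrame) -> pd.Series:
    """aMED (0-9) per subject at one visit via cohort median splits."""
    complete = profiles.dropna(subset=AMED_GOOD + AMED_BAD + ["alcohol_g"])
    if len(complete) < 2:
        raise DegenerateMedianError("aMED medians need at least two subjects")
    total = np.zeros(len(profiles))
    for col in AMED_GOOD:
        med = complete[col].median()
        total += (profiles[col].to_numpy(dtype=float) > med).astype(float)
    for col in AMED_BAD:
        med = complete[col].median()
        total += (profiles[col].to_numpy(dtype=float) < med).astype(float)
    alc = profiles["alcohol_g"].to_numpy(dtype=float)
    lo, hi = AMED_ALCOHOL_WINDOW
    total += ((alc >= lo) & (alc <= hi)).astype(float)
    nan_mask = profiles[AMED_GOOD + AMED_BAD + ["alcohol_g"]].isna().any(axis=1)
    return pd.Series(np.where(nan_mask, np.nan, total), index=profiles.index, name="amed")


DASH_GOOD = ["fruit", "vegetables", "nuts_legumes", "lowfat_dairy", "whole_grains"]
DASH_BAD = ["sodium_mg", "red_processed_meat", "ssb"]


def score_dash(profiles: pd.DataFrame) -> pd.Series:
    """DASH (8-40) per subject at one visit via component quintile ranks."""
    total = np.zeros(len(profiles))
    for col in DASH_GOOD:
        total += quantile_bins(profiles[col], 5).to_numpy(dtype=float)
    for col in DASH_BAD:
        total += 6.0 - quantile_bins(profiles[col], 5).to_numpy(dtype=float)
    return pd.Series(total, index=profiles.index, name="dash")


LC_FIELDS = {
    "total": ("pct_energy_fat_total", "pct_energy_protein_total"),
    "animal": ("pct_energy_fat_animal", "pct_energy_protein_animal"),
    "plant": ("pct_energy_fat_veg", "pct_energy_protein_veg"),
}


def score_low_carbohydrate(profiles: pd.DataFrame, variant: str = "total") -> pd.Series:
    """Low-carbohydrate index (0-30) via eleven quantile strata per macronutrient.

    Ascending strata (0-10 points) for percent energy from fat and protein
    (source selected by ``variant``), descending for carbohydrate.
    """
    if variant not in LC_FIELDS:
        raise ValueError(f"unknown low-carbohydrate variant '{variant}'")
    fat_col, prot_col = LC_FIELDS[variant]
    fat = quantile_bins(profiles[fat_col], 11) - 1.0
    prot = quantile_bins(profiles[prot_col], 11) - 1.0
    carb = 11.0 - quantile_bins(profiles["pct_energy_carb"], 11)
    total = fat.to_numpy(dtype=float) + prot.to_numpy(dtype=float) + carb.to_numpy(dtype=float)
    return pd.Series(total, index=profiles.index, name=f"lc_{variant}")


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def score_indices(intake: pd.DataFrame) -> pd.DataFrame:
    """All six index scores per subject-visit.

    Expects one row per (subject_id, visit_index); median/quantile cut
    points are computed within visit.  Rows with missing intake fields get
    NaN scores (to be filled later by trajectory-mean imputation).
    """
    out = intake[["subject_id", "visit_index"]].copy()
    out["ahei2010"] = score_ahei2010_table(intake)
    for visit, grp in intake.groupby("visit_index"):
        out.loc[grp.index, "amed"] = score_amed(grp)
        out.loc[grp.index, "dash"] = score_dash(grp)
        for variant in ("total", "animal", "plant"):
            out.loc[grp.index, f"lc_{variant}"] = score_low_carbohydrate(grp, variant)
    out["energy_kcal"] = intake["energy_kcal"]
    out["bmi"] = intake["bmi"]
    return out


def rank_and_lag(scores: pd.DataFrame, index_names=None) -> pd.DataFrame:
    """Attach per-visit quintile, trend value, and lagged exposure columns.

    For each index ``x`` adds ``x_quintile``, ``x_trend`` (median score of
    the subject's quintile at that visit), ``x_lag_score`` and
    ``x_lag_quintile`` (from the previous visit; NaN at the first visit).
    """
    index_names = list(index_names or INDEX_NAMES)
    panel = scores.sort_values(["subject_id", "visit_index"]).reset_index(drop=True)
    for name in index_names:
        q = pd.Series(np.nan, index=panel.index)
        for _, grp in panel.groupby("visit_index"):
            q.loc[grp.index] = assign_quintiles(grp[name])
        panel[f"{name}_quintile"] = q
        t = pd.Series(np.nan, index=panel.index)
        for _, grp in panel.groupby("visit_index"):
            t.loc[grp.index] = trend_values(grp[name], q.loc[grp.index])
        panel[f"{name}_trend"] = t
        g = panel.groupby("subject_id")
        panel[f"{name}_lag_score"] = g[name].shift(1)
        panel[f"{name}_lag_quintile"] = g[f"{name}_quintile"].shift(1)
    return panel


def transition_summary(panel: pd.DataFrame, index_name: str) -> dict:
    """Quintile transition counts between adjacent visits plus change labels.

    Returns ``{"matrices": {(v, v+1): 5x5 DataFrame}, "changes": DataFrame}``
    where the change label classifies each subject-transition as
    increase/no change/decrease in quintile ranking.
    """
    col = f"{index_name}_quintile"
    if col not in panel.columns:
        raise KeyError(f"panel has no quintile column for index '{index_name}'")
    visits = sorted(panel["visit_index"].unique())
    if len(visits) < 2:
        raise ValueError("transition summary needs at least two visits")
    wide = panel.pivot(index="subject_id", columns="visit_index", values=col)
    matrices = {}
    records = []
    for v0, v1 in zip(visits[:-1], visits[1:]):
        sub = wide[[v0, v1]].dropna()
        mat = pd.DataFrame(
            0, index=range(1, 6), columns=range(1, 6), dtype=int
        )
        for (a, b), cnt in sub.value_counts().items():
            mat.loc[int(a), int(b)] = cnt
        matrices[(v0, v1)] = mat
        diff = sub[v1] - sub[v0]
        label = np.select([diff > 0, diff < 0], ["increase", "decrease"], "no change")
        for sid, lab in zip(sub.index, label):
            records.append({"subject_id": sid, "from_visit": v0, "to_visit": v1, "change": lab})
    return {"matrices": matrices, "changes": pd.DataFrame(records)}
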