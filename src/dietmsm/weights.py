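"""Stabilized inverse-probability-of-treatment and -censoring weights.

The treatment is the 5-level (quintile) diet-index exposure observed at
each visit.  Stabilized IPTW are cumulative products over visits of the
ratio of two predicted probabilities of the observed level: a numerator
model conditioning on the lagged exposure and baseline covariates, and a
denominator model that adds the time-varying confounders (BMI and caloric
intake) through restricted cubic splines with three knots.  Stabilized
IPCW are the analogous cumulative ratios of predicted probabilities of
remaining uncensored (loss to follow-up only; administrative censoring is
non-informative by construction and is not modeled).  The final weight is
their product, truncated at a percentile of the pooled weight distribution.

First-interval convention: no exposure history exists at the first visit,
so lag terms are dropped there (separate lag-free fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .errors import FittingError, PositivityError
from .splines import rcs_basis, rcs_knots

BASELINE_CATEGORICAL = ["sex", "smoking", "education", "hpv", "stage", "ace27",
                        "treatment", "site"]
BASELINE_CONTINUOUS = ["age", "bmi0", "kcal0"]


@dataclass
class WeightModelSpec:
    """Configuration of the weight models."""

    exposure_model_family: str = "proportional_odds"  # or "multinomial"
    spline_knots_weight_models: int = 3
    truncation_percentile: float = 98.0
    lag_coding: str = "score"  # "score" (continuous) or "quintile"
    censoring_L: str = "current"  # "current" (visit-start L) or "lagged"
    baseline_covariates: list = field(
        default_factory=lambda: BASELINE_CATEGORICAL + BASELINE_CONTINUOUS
    )

    def __post_init__(self):
        if self.spline_knots_weight_models < 3:
            raise ValueError("weight-model splines need at least 3 knots")
        if self.exposure_model_family not in ("proportional_odds", "multinomial"):
            raise ValueError(f"unknown exposure family {self.exposure_model_family}")


def _baseline_design(pp: pd.DataFrame, spec: WeightModelSpec) -> pd.DataFrame:
    cols = [c for c in spec.baseline_covariates if c in pp.columns]
    cat = [c for c in cols if c in BASELINE_CATEGORICAL]
    cont = [c for c in cols if c not in cat]
    parts = []
    if cont:
        parts.append(pp[cont].astype(float))
    if cat:
        parts.append(pd.get_dummies(pp[cat].astype(str), drop_first=True, dtype=float))
    if not parts:
        return pd.DataFrame(index=pp.index)
    return pd.concat(parts, axis=1)


def _lag_design(pp: pd.DataFrame, spec: WeightModelSpec) -> pd.DataFrame:
    if spec.lag_coding == "quintile":
        return pd.get_dummies(
            pp["lag_quintile"].astype("Int64").astype(str), prefix="lagq",
            drop_first=True, dtype=float,
        )
    return pp[["lag_score"]].astype(float)


def _spline_design(pp: pd.DataFrame, spec: WeightModelSpec,
                   tv_cols=("bmi", "energy_kcal"), knots=None) -> tuple[pd.DataFrame, dict]:
    frames, used_knots = [], {}
    for col in tv_cols:
        if col not in pp.columns:
            continue
        x = pp[col].to_numpy(dtype=float)
        if knots is None and np.unique(
            np.quantile(x[~np.isnan(x)], [0.1, 0.5, 0.9])
        ).size < 3:
            continue  # near-constant covariate: no spline expansion possible
        kn = knots[col] if knots else rcs_knots(x, spec.spline_knots_weight_models)
        used_knots[col] = kn
        basis = rcs_basis(x, kn)
        frames.append(
            pd.DataFrame(
                basis,
                columns=[f"{col}_rcs{j}" for j in range(basis.shape[1])],
                index=pp.index,
            )
        )
    if not frames:
        return pd.DataFrame(index=pp.index), used_knots
    return pd.concat(frames, axis=1), used_knots


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    nun = X.nunique()
    return X.loc[:, nun[nun > 1].index]


def _fit_ordinal(endog: pd.Series, X: pd.DataFrame) -> tuple:
    """Fit a proportional-odds model; return (result, categories)."""
    cats = np.sort(endog.unique())
    if len(cats) < 2:
        raise FittingError("exposure has a single observed level")
    y = pd.Series(
        pd.Categorical(endog, categories=cats, ordered=True), index=endog.index
    )
    X = _drop_constant(X)
    # standardize for optimizer stability; predictions are invariant
    mu = X.mean(axis=0)
    sd = X.std(axis=0).replace(0.0, 1.0)
    Xs = (X - mu) / sd
    try:
        if X.shape[1] == 0:
            model = OrderedModel(y, np.zeros((len(endog), 0)), distr="logit")
        else:
            model = OrderedModel(y, Xs.to_numpy(dtype=float), distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="lbfgs", maxiter=300, disp=False)
    except Exception as exc:  # pragma: no cover - statsmodels raises many types
        raise FittingError(f"ordinal exposure model failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FittingError("ordinal exposure model produced non-finite parameters")
    return res, cats, X.columns.tolist(), mu, sd


def _predict_observed_prob_ordinal(fit, X: pd.DataFrame, observed: pd.Series) -> np.ndarray:
    res, cats, cols, mu, sd = fit
    Xs = (X[cols] - mu) / sd
    exog = Xs.to_numpy(dtype=float) if len(cols) else np.zeros((len(observed), 0))
    probs = res.model.predict(res.params, exog=exog)
    col = pd.Categorical(observed, categories=cats).codes
    return probs[np.arange(len(observed)), col]


def _fit_multinomial(endog: pd.Series, X: pd.DataFrame):
    cats = np.sort(endog.unique())
    y = pd.Categorical(endog, categories=cats).codes
    X = _drop_constant(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0).replace(0.0, 1.0)
    Xs = (X - mu) / sd
    exog = (
        sm.add_constant(Xs.to_numpy(dtype=float), has_constant="add")
        if X.shape[1]
        else np.ones((len(endog), 1))
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, exog).fit(method="lbfgs", maxiter=300, disp=False)
    except Exception as exc:  # pragma: no cover
        raise FittingError(f"multinomial exposure model failed: {exc}") from exc
    return res, cats, X.columns.tolist(), mu, sd


def _predict_observed_prob_multinomial(fit, X: pd.DataFrame, observed: pd.Series) -> np.ndarray:
    res, cats, cols, mu, sd = fit
    Xs = (X[cols] - mu) / sd
    exog = (
        sm.add_constant(Xs.to_numpy(dtype=float), has_constant="add")
        if len(cols)
        else np.ones((len(observed), 1))
    )
    probs = res.predict(exog)
    col = pd.Categorical(observed, categories=cats).codes
    return np.asarray(probs)[np.arange(len(observed)), col]


class ExposureModels:
    """Numerator and denominator exposure-probability models.

    Fits are stratified on first interval (no lag terms) versus later
    intervals, pooled across the latter.
    """

    def __init__(self, pp: pd.DataFrame, spec: WeightModelSpec):
        self.spec = spec
        self.p_num = pd.Series(np.nan, index=pp.index)
        self.p_den = pd.Series(np.nan, index=pp.index)
        base = _baseline_design(pp, spec)
        spl, self.knots = _spline_design(pp, spec)
        first = pp["interval"] == pp["interval"].min()
        for mask, with_lag in ((first, False), (~first, True)):
            if not mask.any():
                continue
            sub = pp.loc[mask]
            Xn = base.loc[mask]
            if with_lag:
                Xn = pd.concat([_lag_design(sub, spec), Xn], axis=1)
            Xd = pd.concat([Xn, spl.loc[mask]], axis=1)
            a = sub["A"].astype(int)
            if spec.exposure_model_family == "proportional_odds":
                fit, pred = _fit_ordinal, _predict_observed_prob_ordinal
            else:
                fit, pred = _fit_multinomial, _predict_observed_prob_multinomial
            self.p_num.loc[mask] = pred(fit(a, Xn), Xn, a)
            self.p_den.loc[mask] = pred(fit(a, Xd), Xd, a)


def fit_exposure_models(pp: pd.DataFrame, spec: WeightModelSpec | None = None) -> ExposureModels:
    """Fit numerator/denominator treatment models on pooled person-periods."""
    return ExposureModels(pp, spec or WeightModelSpec())


def stabilized_iptw(pp: pd.DataFrame, models: ExposureModels) -> pd.Series:
    """Cumulative stabilized treatment weights per person-period."""
    p_num, p_den = models.p_num, models.p_den
    if (p_den <= 1e-12).any():
        row = pp.loc[p_den <= 1e-12].iloc[0]
        raise PositivityError(
            f"zero denominator treatment probability for subject "
            f"{row['subject_id']} interval {row['interval']}"
        )
    ratio = p_num / p_den
    df = pp[["subject_id", "interval"]].copy()
    df["ratio"] = ratio
    df = df.sort_values(["subject_id", "interval"])
    sw = df.groupby("subject_id")["ratio"].cumprod()
    return sw.reindex(pp.index).rename("sw_iptw")


class CensoringModels:
    """Pooled logistic models for remaining uncensored (loss to follow-up)."""

    def __init__(self, pp: pd.DataFrame, spec: WeightModelSpec):
        self.spec = spec
        self.p_num = pd.Series(1.0, index=pp.index)
        self.p_den = pd.Series(1.0, index=pp.index)
        censor_col = "censor_ltfu" if "censor_ltfu" in pp.columns else "censor"
        if pp[censor_col].sum() == 0:
            return  # no loss to follow-up anywhere: weights are identically 1
        base = _baseline_design(pp, spec)
        if spec.censoring_L == "lagged":
            tv = pp.groupby("subject_id")[["bmi", "energy_kcal"]].shift(1)
            tv = tv.fillna(pp[["bmi", "energy_kcal"]])
        else:
            tv = pp[["bmi", "energy_kcal"]]
        spl, self.knots = _spline_design(tv, spec, tv_cols=("bmi", "energy_kcal"))
        uncensored = 1 - pp[censor_col].astype(int)
        first = pp["interval"] == pp["interval"].min()
        for mask, with_lag in ((first, False), (~first, True)):
            if not mask.any():
                continue
            sub = pp.loc[mask]
            y = uncensored.loc[mask]
            if y.nunique() == 1:
                if y.iloc[0] == 0:
                    raise FittingError("an interval stratum is entirely censored")
                continue  # nobody censored in this stratum: probabilities stay 1
            Xn = base.loc[mask]
            if with_lag:
                Xn = pd.concat([_lag_design(sub, spec), Xn], axis=1)
            else:
                # at the first interval the 'prior exposure' is the current one
                Xn = pd.concat([sub[["A"]].astype(float), Xn], axis=1)
            Xd = pd.concat([Xn, spl.loc[mask]], axis=1)
            self.p_num.loc[mask] = self._fit_predict(y, Xn)
            self.p_den.loc[mask] = self._fit_predict(y, Xd)

    @staticmethod
    def _fit_predict(y: pd.Series, X: pd.DataFrame) -> np.ndarray:
        X = _drop_constant(X)
        exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y.to_numpy(dtype=float), exog,
                             family=sm.families.Binomial()).fit()
        except Exception as exc:  # pragma: no cover
            raise FittingError(f"censoring model failed: {exc}") from exc
        return np.asarray(res.predict(exog))


def fit_censoring_models(pp: pd.DataFrame, spec: WeightModelSpec | None = None) -> CensoringModels:
    return CensoringModels(pp, spec or WeightModelSpec())


def stabilized_ipcw(pp: pd.DataFrame, models: CensoringModels) -> pd.Series:
    """Cumulative stabilized censoring weights per person-period."""
    ratio = models.p_num / models.p_den
    df = pp[["subject_id", "interval"]].copy()
    df["ratio"] = ratio
    df = df.sort_values(["subject_id", "interval"])
    sw = df.groupby("subject_id")["ratio"].cumprod()
    return sw.reindex(pp.index).rename("sw_ipcw")


def combine_and_truncate(
    sw_iptw: pd.Series, sw_ipcw: pd.Series, percentile: float = 98.0
) -> pd.DataFrame:
    """Final stabilized weights, truncated at a pooled percentile.

    Rows at or above the cut-point are assigned the cut-point value; the
    untruncated weight is retained.
    """
    if not sw_iptw.index.equals(sw_ipcw.index):
        raise ValueError("IPTW and IPCW cover different person-period rows")
    raw = sw_iptw * sw_ipcw
    cap = float(np.percentile(raw, percentile))
    truncated = (raw >= cap) & (percentile < 100.0)
    return pd.DataFrame(
        {
            "sw_iptw": sw_iptw,
            "sw_ipcw": sw_ipcw,
            "sw_raw": raw,
            "sw": np.where(truncated, cap, raw),
            "truncated": truncated,
        },
        index=raw.index,
    )


def compute_stabilized_weights(
    pp: pd.DataFrame, spec: WeightModelSpec | None = None
) -> pd.DataFrame:
    """IPTW x IPCW pipeline for one person-period table."""
    spec = spec or WeightModelSpec()
    exp_models = fit_exposure_models(pp, spec)
    sw_iptw = stabilized_iptw(pp, exp_models)
    cen_models = fit_censoring_models(pp, spec)
    sw_ipcw = stabilized_ipcw(pp, cen_models)
    w = combine_and_truncate(sw_iptw, sw_ipcw, spec.truncation_percentile)
    out = pp[["subject_id", "interval"]].join(w)
    if "index" in pp.columns:
        out.insert(0, "index", pp["index"])
    return out


def weight_diagnostics(weights: pd.DataFrame, warn_band: float = 0.5) -> pd.DataFrame:
    """Per-index, per-visit weight summary (min/max/mean/median).

    Means deviating from 1 by more than ``warn_band`` flag likely weight-model
    misspecification.
    """
    keys = [c for c in ("index", "interval") if c in weights.columns]
    g = weights.groupby(keys)["sw"]
    summary = g.agg(["min", "max", "mean", "median"]).reset_index()
    summary["misspecification_warning"] = (summary["mean"] - 1.0).abs() > warn_band
    return summary
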