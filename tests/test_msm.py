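"""Cox model layer: oracles, identities, dose-response, standardized curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from dietmsm.errors import FittingError
from dietmsm.msm import (
    adjusted_survival_curves,
    continuous_sd_fit,
    fit_baseline_cox,
    fit_msm,
    fit_unweighted,
    interaction_lrt,
    rcs_dose_response,
    sensitivity_censor_imputed,
    trend_test,
)

from conftest import toy_person_periods


def cox_pl_oracle(durations, events, x):
    """Grid/Brent maximizer of the (untied) Cox log partial likelihood."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)

    def neg_ll(beta):
        ll = 0.0
        for t in durations[events]:
            i = np.flatnonzero((durations == t) & events)[0]
            risk = durations >= t
            ll += x[i] * beta - np.log(np.sum(np.exp(x[risk] * beta)))
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


def _untied_toy_pp():
    # 8 subjects, one interval each, untied event times
    recs = [
        ("s1", 1, 0.0, 0.31, 1, 1, 0),
        ("s2", 1, 0.0, 0.47, 2, 0, 0),
        ("s3", 1, 0.0, 0.58, 3, 1, 0),
        ("s4", 1, 0.0, 0.66, 1, 0, 0),
        ("s5", 1, 0.0, 0.79, 4, 1, 0),
        ("s6", 1, 0.0, 0.91, 5, 0, 0),
        ("s7", 1, 0.0, 1.02, 2, 1, 0),
        ("s8", 1, 0.0, 1.19, 3, 0, 0),
    ]
    return toy_person_periods(recs)


class TestOracle:
    def test_unweighted_matches_partial_likelihood_oracle(self):
        pp = _untied_toy_pp()
        fit = fit_unweighted(pp, covariates=[], exposure="linear",
                             lag_coding="none", robust=False)
        beta_oracle = cox_pl_oracle(pp["stop"], pp["event_allcause"] == 1, pp["A"])
        assert fit.params.loc["A"] == pytest.approx(beta_oracle, abs=1e-6)

    def test_baseline_cox_matches_oracle(self):
        pp = _untied_toy_pp()
        subjects = pp.rename(columns={"stop": "duration"})
        fit = fit_baseline_cox(subjects, covariates=[], exposure="linear")
        beta_oracle = cox_pl_oracle(
            subjects["duration"], subjects["event_allcause"] == 1, subjects["A"]
        )
        assert fit.params.loc["A"] == pytest.approx(beta_oracle, abs=1e-6)

    def test_duplicated_dataset_leaves_estimate_stable(self):
        """Row duplication scales the partial likelihood, leaving its argmax
        in place; with Efron tie handling the duplicated copies tie at every
        event time, so equality is approximate rather than exact."""
        pp = _untied_toy_pp()
        dup = pp.copy()
        dup["subject_id"] = dup["subject_id"] + "_dup"
        both = pd.concat([pp, dup], ignore_index=True)
        f1 = fit_unweighted(pp, covariates=[], exposure="linear",
                            lag_coding="none", robust=False)
        f2 = fit_unweighted(both, covariates=[], exposure="linear",
                            lag_coding="none", robust=False)
        assert f1.params.loc["A"] == pytest.approx(f2.params.loc["A"], abs=0.05)


class TestIdentities:
    def test_unit_weights_reproduce_unweighted_fit(self, small_pp):
        pp, _ = small_pp
        ones = pd.Series(1.0, index=pp.index)
        msm = fit_msm(pp, ones, covariates=["age", "female"], exposure="quintile",
                      lag_coding="quintile")
        unw = fit_unweighted(pp, covariates=["age", "female"], exposure="quintile",
                             lag_coding="quintile")
        assert np.allclose(msm.params, unw.params, atol=1e-10)

    def test_robust_se_close_to_model_se_with_unit_weights(self, small_pp):
        pp, _ = small_pp
        ones = pd.Series(1.0, index=pp.index)
        robust = fit_msm(pp, ones, covariates=["age"], exposure="linear",
                         lag_coding="none", robust=True)
        naive = fit_unweighted(pp, covariates=["age"], exposure="linear",
                               lag_coding="none", robust=False)
        ratio = robust.se.loc["A"] / naive.se.loc["A"]
        assert 0.7 < ratio < 1.4

    def test_cancer_fit_identical_when_all_deaths_cancer(self, small_pp):
        pp, _ = small_pp
        df = pp.copy()
        df["event_cancer"] = df["event_allcause"]
        f_all = fit_unweighted(df, covariates=["age"], exposure="linear",
                               lag_coding="none", outcome="all_cause", robust=False)
        f_ca = fit_unweighted(df, covariates=["age"], exposure="linear",
                              lag_coding="none", outcome="cancer", robust=False)
        assert np.allclose(f_all.params, f_ca.params, atol=1e-12)

    def test_no_events_raises(self):
        pp = _untied_toy_pp()
        pp["event_allcause"] = 0
        with pytest.raises(FittingError):
            fit_unweighted(pp, covariates=[], exposure="linear", lag_coding="none")


def _dose_response_pp(n=1500, seed=11, effect="linear", strength=0.5):
    """One-interval cohort with event risk driven by a continuous score."""
    rng = np.random.default_rng(seed)
    score = rng.normal(0.0, 1.0, n)
    if effect == "linear":
        lp = -2.2 + strength * score
    elif effect == "quadratic":
        lp = -2.6 + strength * score**2
    else:
        lp = np.full(n, -2.2)
    event = (rng.random(n) < expit(lp)).astype(int)
    stop = np.where(event == 1, rng.uniform(0.05, 0.95, n), 1.0)
    return pd.DataFrame(
        {
            "subject_id": np.arange(n), "interval": 1, "start": 0.0,
            "stop": stop, "event_allcause": event, "event_cancer": event,
            "A": pd.Series(score).rank(pct=True).mul(4.999).add(0.5).round().clip(1, 5).astype(int),
            "score": score,
        }
    )


class TestTrendAndContinuous:
    def test_constant_trend_raises(self):
        pp = _untied_toy_pp()
        pp["trend"] = 1.0
        with pytest.raises(FittingError):
            trend_test(pp, None, covariates=[], lag_coding="none")

    def test_linear_effect_detected_by_trend(self):
        pp = _dose_response_pp(effect="linear")
        pp["trend"] = pp.groupby("A")["score"].transform("median")
        p, _ = trend_test(pp, None, covariates=[], lag_coding="none")
        assert p < 1e-4

    def test_hr_per_sd_scale_invariant(self):
        pp = _dose_response_pp(effect="linear")
        out1 = continuous_sd_fit(pp, None, covariates=[], lag_coding="none")
        pp10 = pp.assign(score=pp["score"] * 10)
        out10 = continuous_sd_fit(pp10, None, covariates=[], lag_coding="none")
        assert out1["hr_per_sd"] == pytest.approx(out10["hr_per_sd"], rel=1e-8)

    def test_quadratic_term_power_and_calibration(self):
        quad = continuous_sd_fit(
            _dose_response_pp(effect="quadratic", strength=0.5), None,
            covariates=[], lag_coding="none",
        )
        assert quad["p_quadratic"] < 1e-3
        lin = continuous_sd_fit(
            _dose_response_pp(effect="linear"), None, covariates=[], lag_coding="none"
        )
        assert lin["p_quadratic"] > 0.01


class TestDoseResponse:
    def test_hr_at_median_is_one(self):
        pp = _dose_response_pp()
        curve = rcs_dose_response(
            pp, None, covariates=[], lag_coding="none",
            grid=np.array([pp["score"].median()]),
        )
        assert curve.hr[0] == pytest.approx(1.0, abs=1e-12)

    def test_linear_truth_within_spline_band(self):
        pp = _dose_response_pp(effect="linear", strength=0.5, n=4000)
        curve = rcs_dose_response(pp, None, covariates=[], lag_coding="none")
        # reference curve from the linear fit on the same data
        lin = fit_unweighted(
            pp.assign(A=pp["score"]), covariates=[], exposure="linear",
            lag_coding="none", robust=False,
        )
        beta = lin.params.loc["A"]
        truth = np.exp(beta * (curve.grid - curve.reference))
        inside = (curve.hr_lo <= truth) & (truth <= curve.hr_hi)
        assert inside.mean() > 0.9

    def test_affine_shift_invariance(self):
        pp = _dose_response_pp()
        c0 = rcs_dose_response(pp, None, covariates=[], lag_coding="none")
        shifted = pp.assign(score=pp["score"] + 100.0)
        c1 = rcs_dose_response(shifted, None, covariates=[], lag_coding="none")
        assert np.allclose(c0.hr, c1.hr, rtol=1e-6)
        assert np.allclose(c1.knots - c0.knots, 100.0)


class TestInteraction:
    def _pp_with_modifier(self, interaction=0.0, n=3000, seed=21):
        rng = np.random.default_rng(seed)
        pp = _dose_response_pp(n=n, seed=seed, effect="linear", strength=0.3)
        pp["site"] = rng.choice(["oral cavity", "oropharynx", "larynx-hypopharynx"], n)
        if interaction:
            boost = interaction * pp["score"] * (pp["site"] == "oropharynx")
            flip = rng.random(n) < expit(-2.2 + 0.3 * pp["score"] + boost)
            pp["event_allcause"] = flip.astype(int)
            pp["event_cancer"] = pp["event_allcause"]
            pp["stop"] = np.where(pp["event_allcause"] == 1,
                                  rng.uniform(0.05, 0.95, n), 1.0)
        return pp

    def test_single_level_modifier_raises(self):
        pp = self._pp_with_modifier()
        pp["site"] = "oral cavity"
        with pytest.raises(FittingError):
            interaction_lrt(pp, None, "site", covariates=[], lag_coding="none")

    def test_homogeneous_effect_not_flagged(self):
        out = interaction_lrt(
            self._pp_with_modifier(0.0), None, "site", covariates=[], lag_coding="none"
        )
        assert out["p_lrt"] > 0.01
        assert set(out["strata"]) == {"oral cavity", "oropharynx", "larynx-hypopharynx"}

    def test_stratum_specific_effect_detected(self):
        out = interaction_lrt(
            self._pp_with_modifier(0.8), None, "site", covariates=[], lag_coding="none"
        )
        assert out["p_lrt"] < 1e-3
        hrs = {k: v["hr_per_sd"] for k, v in out["strata"].items()}
        assert hrs["oropharynx"] > hrs["oral cavity"]


class TestAdjustedCurves:
    def test_zero_coefficient_model_gives_identical_curves(self, small_pp):
        pp, _ = small_pp
        ones = pd.Series(1.0, index=pp.index)
        fit = fit_msm(pp, ones, covariates=["age"], exposure="quintile",
                      lag_coding="none")
        fit.params.loc[:] = 0.0
        curves = adjusted_survival_curves(fit)
        for q in ["Q2", "Q3", "Q4", "Q5"]:
            assert np.allclose(curves[q], curves["Q1"], atol=1e-12)

    def test_protective_high_quintile_orders_curves(self):
        rng = np.random.default_rng(8)
        n = 4000
        a = rng.integers(1, 6, n)
        event = (rng.random(n) < expit(-1.4 - 0.8 * (a == 5))).astype(int)
        stop = np.where(event == 1, rng.uniform(0.05, 0.95, n), 1.0)
        pp = pd.DataFrame(
            {"subject_id": np.arange(n), "interval": 1, "start": 0.0,
             "stop": stop, "event_allcause": event, "event_cancer": event,
             "A": a, "score": a.astype(float)}
        )
        fit = fit_unweighted(pp, covariates=[], exposure="quintile", lag_coding="none",
                             robust=False)
        curves = adjusted_survival_curves(fit)
        assert (curves["Q5"] >= curves["Q1"]).all()

    def test_curves_monotone_nonincreasing(self, small_pp):
        pp, _ = small_pp
        fit = fit_unweighted(pp, covariates=["age"], exposure="quintile",
                             lag_coding="none", robust=False)
        curves = adjusted_survival_curves(fit)
        assert (curves.diff().dropna() <= 1e-12).all().all()


class TestSensitivity:
    def test_no_imputed_records_identical(self, small_pp):
        pp, _ = small_pp
        df = pp.copy()
        df["imputed_flag"] = False
        out = sensitivity_censor_imputed(
            df, covariates=["age", "female"], exposure="linear", lag_coding="none"
        )
        assert np.allclose(out["comparison"]["difference"], 0.0, atol=1e-12)
        assert out["primary"].n_person_periods == out["sensitivity"].n_person_periods

    def test_flagged_subjects_censored_early(self, small_pp):
        pp, _ = small_pp
        df = pp.copy()
        df["imputed_flag"] = False
        multi = df.groupby("subject_id")["interval"].max()
        flagged = multi[multi == 3].index[:40]
        df.loc[df["subject_id"].isin(flagged) & (df["interval"] == 2), "imputed_flag"] = True
        out = sensitivity_censor_imputed(
            df, covariates=["age", "female"], exposure="linear", lag_coding="none"
        )
        assert out["sensitivity"].n_person_periods < out["primary"].n_person_periods
        diff = out["comparison"].loc["A", "difference"]
        assert abs(diff) < 0.1
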