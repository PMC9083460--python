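"""Diet-index scoring: bounds, hand-computed oracles, rank invariance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietmsm.errors import (
    DegenerateDistributionError,
    DegenerateMedianError,
    RankingError,
    ScoringError,
)
from dietmsm.scores import (
    AHEI_COMPONENTS,
    assign_quintiles,
    quantile_bins,
    score_ahei2010,
    score_ahei2010_table,
    score_amed,
    score_dash,
    score_low_carbohydrate,
    transition_summary,
    trend_values,
)


def _profile_from_extremes(intake, which, visit=0):
    row = intake[(intake.subject_id == which) & (intake.visit_index == visit)]
    return row.iloc[0]


class TestAHEI:
    def test_maximal_profile_scores_110(self, intake_with_extremes):
        best = _profile_from_extremes(intake_with_extremes, "BEST")
        assert score_ahei2010(best) == pytest.approx(110.0)

    def test_minimal_profile_scores_0(self, intake_with_extremes):
        worst = _profile_from_extremes(intake_with_extremes, "WORST")
        assert score_ahei2010(worst) == pytest.approx(0.0)

    def test_midpoint_profile_sums_component_midpoints(self):
        # each interpolated component exactly halfway between floor and
        # ceiling contributes 5 points; alcohol at the midpoint of the
        # decline segment (25 g/day between 15 and 35) contributes 5 too
        profile = {
            field: (lo + hi) / 2.0 for field, lo, hi in AHEI_COMPONENTS.values()
        }
        profile["alcohol_g"] = 25.0
        assert score_ahei2010(profile) == pytest.approx(55.0)

    def test_missing_field_raises_named_error(self):
        with pytest.raises(ScoringError, match="vegetables"):
            score_ahei2010({"fruit": 1.0, "alcohol_g": 0.0})

    def test_table_matches_scalar_scorer(self, intake_with_extremes):
        v0 = intake_with_extremes[intake_with_extremes.visit_index == 0]
        vec = score_ahei2010_table(v0)
        scalar = v0.apply(score_ahei2010, axis=1)
        assert np.allclose(vec, scalar)

    @given(
        veg=st.floats(0, 20),
        extra=st.floats(0.1, 5.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_rewarded_component_monotone(self, veg, extra):
        base = {f: lo for f, lo, hi in AHEI_COMPONENTS.values()}
        base["alcohol_g"] = 10.0
        lower = dict(base, vegetables=veg)
        higher = dict(base, vegetables=veg + extra)
        assert score_ahei2010(higher) >= score_ahei2010(lower)

    def test_range_invariant_on_random_profiles(self, intake_with_extremes):
        scores = score_ahei2010_table(intake_with_extremes)
        assert scores.between(0.0, 110.0).all()


class TestAMed:
    def test_designated_subject_scores_9(self, intake_with_extremes):
        v0 = intake_with_extremes[intake_with_extremes.visit_index == 0]
        s = score_amed(v0)
        assert s[v0.subject_id == "BEST"].iloc[0] == 9.0
        assert s.between(0, 9).all()

    def test_alcohol_window_component(self):
        # two-subject cohort: only the alcohol component can differ since
        # with n=2 each subject is at or below the median on every split
        cols = ["vegetables", "legumes", "fruit", "nuts", "cereal", "fish",
                "mufa_sfa_ratio", "red_processed_meat"]
        df = pd.DataFrame({c: [1.0, 1.0] for c in cols})
        df["alcohol_g"] = [10.0, 40.0]
        s = score_amed(df)
        assert s.tolist() == [1.0, 0.0]

    def test_four_subject_hand_computed(self):
        # medians: veg 2.5, legumes 0.55, fruit 1.5, nuts 0.35, cereal 1.5,
        # fish 0.75, mufa 1.05, meat 1.15
        df = pd.DataFrame(
            {
                "vegetables": [1, 2, 3, 4],
                "legumes": [0.1, 0.4, 0.7, 1.0],
                "fruit": [0, 1, 2, 3],
                "nuts": [0.1, 0.2, 0.5, 0.9],
                "cereal": [1, 1, 2, 3],
                "fish": [0.5, 0.5, 1.0, 2.0],
                "mufa_sfa_ratio": [0.9, 1.0, 1.1, 1.3],
                "red_processed_meat": [2.0, 1.3, 1.0, 0.5],
                "alcohol_g": [0.0, 10.0, 20.0, 5.0],
            }
        )
        # subject 4: above median on all goods (4>2.5, 1>0.55, 3>1.5,
        # 0.9>0.35, 3>1.5, 2>0.75, 1.3>1.05), meat 0.5<1.15, alcohol 5 in
        # window -> 9; subject 1: nothing; subject 2: alcohol only;
        # subject 3: veg/legumes/fruit/nuts/cereal/fish/mufa above, meat
        # below -> 8, alcohol 20 outside -> 8
        assert score_amed(df).tolist() == [0.0, 1.0, 8.0, 9.0]

    def test_single_subject_raises(self):
        df = pd.DataFrame(
            {c: [1.0] for c in ["vegetables", "legumes", "fruit", "nuts",
                                "cereal", "fish", "mufa_sfa_ratio",
                                "red_processed_meat", "alcohol_g"]}
        )
        with pytest.raises(DegenerateMedianError):
            score_amed(df)


def brute_force_bins(values, n_bins):
    """Independent sort-and-split oracle with ties to the lower bin."""
    values = list(values)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    pos_bin = [int(np.ceil((p + 1) * n_bins / n)) for p in range(n)]
    result = [None] * n
    # ties take the bin of the first (lowest) position in their tie group
    first_pos_of_value = {}
    for p, i in enumerate(order):
        v = values[i]
        if v not in first_pos_of_value:
            first_pos_of_value[v] = p
    for p, i in enumerate(order):
        result[i] = pos_bin[first_pos_of_value[values[i]]]
    return result


class TestDash:
    def test_designated_subject_scores_40(self, intake_with_extremes):
        v0 = intake_with_extremes[intake_with_extremes.visit_index == 0]
        s = score_dash(v0)
        assert s[v0.subject_id == "BEST"].iloc[0] == 40.0
        assert s[v0.subject_id == "WORST"].iloc[0] == 8.0
        assert s.between(8, 40).all()

    def test_component_ranks_match_brute_force(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {c: rng.gamma(2, 1, 10) for c in
             ["fruit", "vegetables", "nuts_legumes", "lowfat_dairy",
              "whole_grains", "sodium_mg", "red_processed_meat", "ssb"]}
        )
        expected = np.zeros(10)
        for c in ["fruit", "vegetables", "nuts_legumes", "lowfat_dairy", "whole_grains"]:
            expected += brute_force_bins(df[c], 5)
        for c in ["sodium_mg", "red_processed_meat", "ssb"]:
            expected += 6 - np.array(brute_force_bins(df[c], 5))
        assert score_dash(df).tolist() == expected.tolist()

    def test_too_few_subjects_raises(self):
        df = pd.DataFrame({c: [1.0, 2.0] for c in
                           ["fruit", "vegetables", "nuts_legumes", "lowfat_dairy",
                            "whole_grains", "sodium_mg", "red_processed_meat", "ssb"]})
        with pytest.raises(RankingError):
            score_dash(df)


class TestLowCarbohydrate:
    def test_extreme_subjects_hit_bounds(self, intake_with_extremes):
        v0 = intake_with_extremes[intake_with_extremes.visit_index == 0]
        s = score_low_carbohydrate(v0, "total")
        assert s[v0.subject_id == "BEST"].iloc[0] == 30.0
        assert s[v0.subject_id == "WORST"].iloc[0] == 0.0
        assert s.between(0, 30).all()

    def test_strata_match_brute_force_on_22_subjects(self):
        rng = np.random.default_rng(7)
        carb = rng.uniform(0.3, 0.7, 22)
        prot = rng.uniform(0.1, 0.25, 22)
        fat = 1 - carb - prot
        df = pd.DataFrame(
            {"pct_energy_carb": carb, "pct_energy_protein_total": prot,
             "pct_energy_fat_total": fat}
        )
        got = score_low_carbohydrate(df, "total")
        expected = (
            np.array(brute_force_bins(fat, 11)) - 1
            + np.array(brute_force_bins(prot, 11)) - 1
            + 11 - np.array(brute_force_bins(carb, 11))
        )
        assert got.tolist() == expected.tolist()

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            score_low_carbohydrate(pd.DataFrame(), "vegan")

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"pct_energy_carb": rng.uniform(0.3, 0.7, 30),
             "pct_energy_protein_total": rng.uniform(0.1, 0.3, 30),
             "pct_energy_fat_total": rng.uniform(0.1, 0.4, 30)}
        )
        before = score_low_carbohydrate(df, "total")
        transformed = df.copy()
        transformed["pct_energy_fat_total"] = np.exp(df["pct_energy_fat_total"] * 3)
        after = score_low_carbohydrate(transformed, "total")
        assert before.tolist() == after.tolist()


class TestQuintiles:
    def test_scores_1_to_100(self):
        q = assign_quintiles(pd.Series(np.arange(1, 101, dtype=float)))
        assert (q.iloc[:20] == 1).all() and (q.iloc[-20:] == 5).all()

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateDistributionError):
            assign_quintiles(pd.Series(np.ones(25)))

    def test_five_way_tie_at_boundary_goes_low(self):
        # 100 values; positions 39-43 (1-based) share one value, straddling
        # the Q2/Q3 boundary at 40 -> all five must land in Q2
        vals = np.arange(1.0, 101.0)
        vals[38:43] = 39.0
        q = assign_quintiles(pd.Series(vals))
        assert (q.iloc[38:43] == 2).all()

    @pytest.mark.parametrize("n,seed", [(13, 0), (37, 1), (50, 2)])
    def test_matches_sort_and_split_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 40, n).astype(float)  # integer scores force ties
        if len(np.unique(vals)) == 1:
            vals[0] += 1
        got = assign_quintiles(pd.Series(vals))
        assert got.tolist() == brute_force_bins(vals, 5)

    def test_nan_propagates_and_quantiles_use_observed_only(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, np.nan])
        q = quantile_bins(vals, 5)
        assert np.isnan(q.iloc[-1])
        assert q.iloc[:5].tolist() == [1, 2, 3, 4, 5]


class TestTrendValues:
    def test_quintile_median_assignment(self):
        scores = pd.Series([10.0, 12.0, 14.0, 20.0, 30.0])
        quintiles = pd.Series([1, 1, 1, 2, 3])
        t = trend_values(scores, quintiles)
        assert t.tolist() == [12.0, 12.0, 12.0, 20.0, 30.0]

    def test_even_sized_group_uses_midpoint(self):
        t = trend_values(pd.Series([10.0, 20.0]), pd.Series([1, 1]))
        assert t.tolist() == [15.0, 15.0]


class TestTransitions:
    def _panel(self, quintiles_by_visit):
        rows = []
        for visit, qs in enumerate(quintiles_by_visit):
            for i, q in enumerate(qs):
                rows.append({"subject_id": f"s{i}", "visit_index": visit,
                             "idx_quintile": q})
        return pd.DataFrame(rows)

    def test_identity_transitions(self):
        panel = self._panel([[1, 2, 3], [1, 2, 3]])
        out = transition_summary(panel, "idx")
        mat = out["matrices"][(0, 1)]
        assert np.trace(mat.to_numpy()) == 3 and mat.to_numpy().sum() == 3
        assert (out["changes"]["change"] == "no change").all()

    def test_hand_counted_matrix_and_labels(self):
        panel = self._panel([[1, 1, 2, 3, 5, 5], [2, 1, 1, 3, 4, 5]])
        out = transition_summary(panel, "idx")
        mat = out["matrices"][(0, 1)]
        assert mat.loc[1, 2] == 1 and mat.loc[1, 1] == 1 and mat.loc[2, 1] == 1
        assert mat.loc[3, 3] == 1 and mat.loc[5, 4] == 1 and mat.loc[5, 5] == 1
        counts = out["changes"]["change"].value_counts()
        assert counts["increase"] == 1 and counts["decrease"] == 2 and counts["no change"] == 3

    def test_row_sums_conserve_subjects(self):
        panel = self._panel([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1], [1, 1, 1, 1, 1]])
        out = transition_summary(panel, "idx")
        for mat in out["matrices"].values():
            assert mat.to_numpy().sum() == 5
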