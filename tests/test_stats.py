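import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

from coelomic.stats import (
    StatsError,
    check_assumptions,
    emm_lsd_pairwise,
    mortality_chi_square,
    percent_range_variation,
    residual_factor_check,
    significance_pattern,
    two_way_anova_type3,
)


def balanced_frame(cell_values, n=None, noise=None, seed=0):
    """Balanced 2x3 data from a dict {(level, temp): [values...]}."""
    rows = []
    rng = np.random.default_rng(seed)
    for (level, temp), values in cell_values.items():
        if n is not None:
            values = list(values) * 0 + list(
                np.asarray(values) + (rng.normal(0, noise, n) if noise else 0)
            )
        for v in values:
            rows.append({"pco2_level": level, "temperature_c": temp, "y": v})
    return pd.DataFrame(rows)


def hand_balanced_anova(df):
    """Textbook cell-means two-way ANOVA for balanced data (the oracle)."""
    cells = df.groupby(["pco2_level", "temperature_c"])["y"]
    n = cells.size().iloc[0]
    a_means = df.groupby("pco2_level")["y"].mean()
    b_means = df.groupby("temperature_c")["y"].mean()
    cell_means = cells.mean()
    grand = df["y"].mean()
    a, b = len(a_means), len(b_means)
    ss_a = n * b * ((a_means - grand) ** 2).sum()
    ss_b = n * a * ((b_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    fitted = df.groupby(["pco2_level", "temperature_c"])["y"].transform("mean")
    ss_err = ((df["y"] - fitted) ** 2).sum()
    return {"pCO2": ss_a, "Temperature": ss_b, "Interaction": ss_ab,
            "Error": ss_err}


BALANCED = balanced_frame(
    {
        ("ambient", 10): [3.1, 2.9, 3.4], ("ambient", 15): [4.0, 4.4, 3.8],
        ("ambient", 20): [2.2, 2.6, 2.1], ("elevated", 10): [5.0, 5.3, 4.8],
        ("elevated", 15): [6.1, 5.7, 6.2], ("elevated", 20): [3.9, 4.2, 4.4],
    }
)


class TestTypeIIIAnova:
    def test_balanced_type3_matches_hand_cell_means_anova(self):
        res = two_way_anova_type3(BALANCED, "y")
        oracle = hand_balanced_anova(BALANCED)
        got = dict(zip(res.table["source"], res.table["ss_type3"]))
        for term, ss in oracle.items():
            assert got[term] == pytest.approx(ss, rel=1e-8), term

    def test_balanced_type3_equals_sequential(self):
        res = two_way_anova_type3(BALANCED, "y")
        a1 = anova_lm(res.model, typ=1)
        a1 = a1.rename(index=lambda s: s.strip())
        t3 = dict(zip(res.table["source"], res.table["ss_type3"]))
        assert t3["pCO2"] == pytest.approx(a1.iloc[0]["sum_sq"], rel=1e-8)
        assert t3["Temperature"] == pytest.approx(a1.iloc[1]["sum_sq"], rel=1e-8)
        assert t3["Interaction"] == pytest.approx(a1.iloc[2]["sum_sq"], rel=1e-8)

    def test_ss_additivity_on_balanced_data(self):
        res = two_way_anova_type3(BALANCED, "y")
        t = res.table.set_index("source")
        parts = t.loc[["pCO2", "Temperature", "Interaction", "Error"], "ss_type3"].sum()
        assert parts == pytest.approx(t.loc["Total corrected", "ss_type3"], rel=1e-8)

    def test_saturated_fit_reports_zero_p(self):
        df = balanced_frame(
            {("ambient", 10): [1.0, 1.0], ("ambient", 20): [2.0, 2.0],
             ("elevated", 10): [3.0, 3.0], ("elevated", 20): [4.0, 4.0]}
        )
        res = two_way_anova_type3(df, "y")
        t = res.table.set_index("source")
        assert t.loc["Error", "ss_type3"] == pytest.approx(0.0, abs=1e-12)
        assert t.loc["pCO2", "p"] == 0.0
        assert np.isinf(t.loc["pCO2", "f"])

    def test_empty_cell_rejected(self):
        df = BALANCED[~((BALANCED.pco2_level == "ambient") &
                        (BALANCED.temperature_c == 20))]
        with pytest.raises(StatsError, match="empty cells"):
            two_way_anova_type3(df, "y")

    def test_log10_transform_requires_positive(self):
        df = BALANCED.copy()
        df.loc[0, "y"] = -1.0
        with pytest.raises(StatsError, match="positive"):
            two_way_anova_type3(df, "y", transform="log10")

    def test_noise_covariate_screened_out_informative_kept(self):
        rng = np.random.default_rng(5)
        df = balanced_frame(
            {c: list(rng.normal(m, 0.4, 12))
             for c, m in zip(
                 itertools.product(["ambient", "elevated"], [10, 15, 20]),
                 [3, 4, 2, 5, 6, 4],
             )}
        )
        df["junk"] = rng.normal(size=len(df))
        df["size_cov"] = rng.normal(size=len(df))
        df["y"] = df["y"] + 2.0 * df["size_cov"]
        res = two_way_anova_type3(df, "y", covariates=["junk", "size_cov"])
        assert res.dropped_covariates == ["junk"]
        assert "size_cov" in set(res.table["source"])

    def test_adj_r2_matches_statsmodels(self):
        res = two_way_anova_type3(BALANCED, "y")
        assert res.adj_r2 == pytest.approx(res.model.rsquared_adj)


class TestEMMLSD:
    def test_identical_groups_share_a_letter_with_p_one(self):
        df = balanced_frame(
            {("ambient", 10): [1.0, 2.0, 3.0], ("ambient", 20): [1.0, 2.0, 3.0],
             ("elevated", 10): [1.0, 2.0, 3.0], ("elevated", 20): [1.0, 2.0, 3.0]}
        )
        res = two_way_anova_type3(df, "y")
        emm = emm_lsd_pairwise(res, "pco2_level")
        assert emm.pairwise["p"].iloc[0] == pytest.approx(1.0)
        assert len(set(emm.letters.values())) == 1

    def test_far_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(2)
        df = balanced_frame(
            {(lv, t): list(rng.normal(0, 0.5, 10))
             for lv in ("ambient", "elevated") for t in (10, 15, 20)}
        )
        df.loc[df.temperature_c == 20, "y"] += 50.0  # >> 10 SE
        res = two_way_anova_type3(df, "y")
        emm = emm_lsd_pairwise(res, "temperature_c")
        assert emm.letters[20] not in (emm.letters[10], emm.letters[15])
        assert emm.letters[10] == emm.letters[15]

    def test_lsd_p_equals_pooled_two_sample_t(self):
        res = two_way_anova_type3(BALANCED, "y")
        emm = emm_lsd_pairwise(res, "pco2_level")
        t_table = res.table.set_index("source")
        mse = t_table.loc["Error", "ms"]
        dfe = t_table.loc["Error", "df"]
        m = BALANCED.groupby("pco2_level")["y"].agg(["mean", "size"])
        t_hand = (m.loc["ambient", "mean"] - m.loc["elevated", "mean"]) / np.sqrt(
            mse * (1 / m.loc["ambient", "size"] + 1 / m.loc["elevated", "size"])
        )
        p_hand = 2 * sps.t.sf(abs(t_hand), dfe)
        assert abs(emm.pairwise["t"].iloc[0]) == pytest.approx(abs(t_hand), rel=1e-9)
        assert emm.pairwise["p"].iloc[0] == pytest.approx(p_hand, rel=1e-9)

    def test_lsd_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(8)
        df = balanced_frame(
            {(lv, t): list(rng.normal(t / 10, 1.0, 8))
             for lv in ("ambient", "elevated") for t in (10, 15, 20)}
        )
        res = two_way_anova_type3(df, "y")
        emm = emm_lsd_pairwise(res, "temperature_c")
        m = len(emm.pairwise)
        bonf = np.minimum(emm.pairwise["p"] * m, 1.0)
        assert (emm.pairwise["p"] <= bonf + 1e-15).all()

    def test_absent_factor_rejected(self):
        res = two_way_anova_type3(BALANCED, "y")
        with pytest.raises(StatsError, match="factor"):
            emm_lsd_pairwise(res, "salinity")


class TestAssumptions:
    @staticmethod
    def _frame(draw, seed=123, n=20):
        rng = np.random.default_rng(seed)
        return balanced_frame(
            {(lv, t): list(draw(rng, n))
             for lv in ("ambient", "elevated") for t in (10, 15, 20)}
        )

    def test_normal_data_passes_raw(self):
        df = self._frame(lambda rng, n: rng.normal(5, 1, n))
        rep = check_assumptions(df, "y")
        assert rep.shapiro_p > 0.05 and rep.levene_p > 0.05
        assert rep.recommendation == "none"

    def test_lognormal_data_recommends_log10(self):
        df = self._frame(lambda rng, n: np.exp(rng.normal(0, 1.2, n)), seed=42, n=40)
        rep = check_assumptions(df, "y")
        assert rep.recommendation == "log10"
        assert rep.log10_shapiro_p > 0.05

    def test_constant_response_flagged_degenerate(self):
        df = self._frame(lambda rng, n: np.full(n, 3.3))
        rep = check_assumptions(df, "y")
        assert rep.degenerate
        assert rep.levene_p == 1.0

    def test_nonpositive_data_proceeds_on_raw_scale(self):
        df = self._frame(lambda rng, n: rng.exponential(2, n) ** 2 - 0.5, seed=9, n=40)
        rep = check_assumptions(df, "y")
        assert rep.recommendation == "proceed_anyway"


class TestResidualFactorCheck:
    def test_modeled_factors_have_orthogonal_residuals(self):
        res = two_way_anova_type3(BALANCED, "y")
        chk = residual_factor_check(res)
        assert (chk["p"] > 0.99).all()
        assert (chk["f"] < 1e-20).all()

    def test_injected_unmodeled_shift_detected(self):
        rng = np.random.default_rng(3)
        df = balanced_frame(
            {(lv, t): list(rng.normal(0, 0.5, 12))
             for lv in ("ambient", "elevated") for t in (10, 15, 20)}
        )
        df["batch"] = np.tile(["b1", "b2"], len(df) // 2)
        df.loc[df["batch"] == "b2", "y"] += 3.0
        res = two_way_anova_type3(df, "y")
        chk = residual_factor_check(res, factors=("batch",))
        # oracle: one-way ANOVA of the residuals by hand
        resid = np.asarray(res.model.resid)
        f_oracle, p_oracle = sps.f_oneway(
            resid[(df["batch"] == "b1").to_numpy()],
            resid[(df["batch"] == "b2").to_numpy()],
        )
        assert chk.loc[0, "p"] == pytest.approx(p_oracle)
        assert chk.loc[0, "p"] < 0.05

    def test_zero_residuals_flagged_degenerate(self):
        df = balanced_frame(
            {("ambient", 10): [1.0, 1.0], ("ambient", 20): [2.0, 2.0],
             ("elevated", 10): [3.0, 3.0], ("elevated", 20): [4.0, 4.0]}
        )
        res = two_way_anova_type3(df, "y")
        chk = residual_factor_check(res)
        assert chk["degenerate"].all()


class TestVariationAndMortality:
    def test_printed_extremes_give_36_55_percent(self):
        v = percent_range_variation([5.50, 7.51])
        assert v.percent_range == 36.55

    @pytest.mark.parametrize(
        "values,expected",
        [([3.3, 3.3, 3.3], 0.0), ([2, 3, 4], 100.0)],
    )
    def test_simple_ranges(self, values, expected):
        assert percent_range_variation(values).percent_range == expected

    def test_nonpositive_minimum_rejected(self):
        with pytest.raises(StatsError, match="nonpositive"):
            percent_range_variation([0.0, 2.0])

    def test_proportional_table_has_zero_chi2(self):
        chi2, dof, p = mortality_chi_square([[10, 5], [20, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        chi2, dof, p = mortality_chi_square([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert dof == 1

    def test_four_group_table_has_df_3(self):
        _, dof, _ = mortality_chi_square([[20, 1], [19, 2], [21, 3], [22, 1]])
        assert dof == 3

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError, match="margin"):
            mortality_chi_square([[0, 0], [3, 4]])


def table1_pvalues():
    """Published factorial p-values for the two calculated responses under
    the three pK'1 strategies (pCO2 / HCO3 responses x pCO2, Temperature,
    Interaction terms)."""
    rows = []
    data = {
        ("individual", "pCO2"): (0.215, 1e-5, 0.098),
        ("individual", "HCO3"): (1e-5, 1e-5, 0.566),
        ("species-mean", "pCO2"): (0.119, 1e-5, 0.036),
        ("species-mean", "HCO3"): (1e-5, 0.009, 0.425),
        ("cross-species", "pCO2"): (0.103, 1e-5, 0.012),
        ("cross-species", "HCO3"): (1e-5, 0.002, 0.508),
    }
    for (approach, response), (p_c, p_t, p_i) in data.items():
        for term, p in zip(("pCO2", "Temperature", "Interaction"), (p_c, p_t, p_i)):
            rows.append({"approach": approach, "response": response,
                         "term": term, "p": p})
    return pd.DataFrame(rows)


class TestSignificancePattern:
    def test_published_pvalues_flag_pco2_interaction_only(self):
        pat = significance_pattern(table1_pvalues(), alpha=0.05)
        diffs = set(map(tuple, pat.diff[["response", "term"]].values))
        assert ("pCO2", "Interaction") in diffs
        # the bicarbonate pCO2 main effect is concordant everywhere
        assert ("HCO3", "pCO2") not in diffs
        hco3 = pat.pattern.query("response == 'HCO3' and term == 'pCO2'")
        assert hco3["significant"].all()

    def test_identical_tables_give_empty_diff(self):
        pv = table1_pvalues()
        pv = pv[pv["approach"] == "individual"]
        pv = pd.concat(
            [pv.assign(approach=a) for a in ("a", "b", "c")], ignore_index=True
        )
        assert significance_pattern(pv).diff.empty

    def test_diff_set_shrinks_with_stricter_alpha(self):
        pv = table1_pvalues()
        d05 = set(map(tuple, significance_pattern(pv, 0.05).diff[["response", "term"]].values))
        d01 = set(map(tuple, significance_pattern(pv, 0.01).diff[["response", "term"]].values))
        assert d01 <= d05

    def test_mismatched_grids_rejected(self):
        pv = table1_pvalues().iloc[:-1]
        with pytest.raises(StatsError, match="grid"):
            significance_pattern(pv)
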