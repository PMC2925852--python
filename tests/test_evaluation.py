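"""Performance statistics: accuracy, precision, dissimilarity, bias tests, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylosel.criteria import CRITERIA
from phylosel.evaluation import (
    accuracy,
    agreement_profile,
    chi2_homogeneity,
    dissimilarity,
    dissimilarity_table,
    model_bias_tables,
    performance_table,
    precision,
    randomized_block_anova,
)


class TestBasicStatistics:
    @pytest.mark.parametrize("matched,total,expected", [
        (46, 100, 46.0), (0, 10, 0.0), (10, 10, 100.0)])
    def test_accuracy_ratio(self, matched, total, expected):
        sel = ["HKY"] * matched + ["JC"] * (total - matched)
        assert accuracy(sel, "HKY") == pytest.approx(expected)

    def test_precision_counts_distinct_models(self):
        assert precision(["A", "A", "A"]) == 1
        assert precision(["A", "A", "B"]) == 2
        assert precision(list("ABCDEFG")) == 7

    def test_dissimilarity_endpoints(self):
        assert dissimilarity(["A", "B"], ["A", "B"]) == 0.0
        assert dissimilarity(["A", "B"], ["C", "D"]) == 100.0
        sel1 = ["M"] * 97 + ["X", "Y", "Z"]
        sel2 = ["M"] * 97 + ["P", "Q", "R"]
        assert dissimilarity(sel1, sel2) == pytest.approx(3.0)

    def test_dissimilarity_length_mismatch(self):
        with pytest.raises(ValueError):
            dissimilarity(["A"], ["A", "B"])

    @given(st.lists(st.tuples(st.sampled_from("ABCDE"),
                              st.sampled_from("ABCDE")),
                    min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_dissimilarity_symmetric_and_bounded(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        d1, d2 = dissimilarity(a, b), dissimilarity(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 100.0

    def test_accuracy_100_implies_precision_1(self):
        sel = ["GTR+I+G"] * 25
        assert accuracy(sel, "GTR+I+G") == 100.0
        assert precision(sel) == 1


class TestAgreementProfile:
    def test_unanimous_profile(self):
        prof = agreement_profile([("A", "A", "A", "A")] * 10)
        assert np.allclose(prof, [100.0, 0.0, 0.0, 0.0])

    def test_counts_distinct_models_per_dataset(self):
        rows = [("A", "A", "B", "B"), ("A", "B", "C", "D"),
                ("A", "A", "A", "C"), ("A", "A", "A", "A")]
        prof = agreement_profile(rows)
        assert np.allclose(prof, [25.0, 50.0, 0.0, 25.0])

    @given(st.lists(st.tuples(*[st.sampled_from("ABC")] * 4),
                    min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_profile_sums_to_100(self, rows):
        assert agreement_profile(rows).sum() == pytest.approx(100.0, abs=1e-9)

    def test_one_model_pct_consistent_with_pairwise_agreement(self):
        rng = np.random.default_rng(0)
        rows = [tuple(rng.choice(["A", "B"], size=4)) for _ in range(200)]
        prof = agreement_profile(rows)
        pct_any_disagree = 100.0 * np.mean(
            [len(set(r)) > 1 for r in rows])
        assert prof[0] == pytest.approx(100.0 - pct_any_disagree)


class TestChiSquareHomogeneity:
    def test_identical_rows_give_zero_statistic(self):
        stat, df, p = chi2_homogeneity(np.array([[10, 20, 30, 40],
                                                 [10, 20, 30, 40]]))
        assert stat == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_hand_built_2x4_matches_expected_count_formula(self):
        table = np.array([[12.0, 30.0, 8.0, 50.0],
                          [20.0, 25.0, 15.0, 40.0]])
        row = table.sum(1, keepdims=True)
        col = table.sum(0, keepdims=True)
        exp = row * col / table.sum()
        want = ((table - exp) ** 2 / exp).sum()
        stat, df, _ = chi2_homogeneity(table)
        assert stat == pytest.approx(want)
        # cross-check against scipy's contingency machinery
        from scipy.stats import chi2_contingency
        ref = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)

    def test_bonferroni_threshold_for_six_pairs(self):
        sel = pd.DataFrame({
            "true_model": ["JC"] * 8,
            "hLRT": ["JC"] * 8, "AIC": ["JC"] * 8,
            "BIC": ["JC"] * 8, "DT": ["JC"] * 8})
        out = model_bias_tables(sel, "category")
        assert out["alpha_corrected"] == pytest.approx(0.05 / 6)
        assert out["alpha_corrected"] == pytest.approx(0.0083, abs=5e-5)

    def test_zero_count_columns_pooled(self):
        sel = pd.DataFrame({
            "true_model": ["JC"] * 4 + ["JC+G"] * 4,
            "hLRT": ["JC"] * 4 + ["JC+G"] * 4,
            "AIC": ["JC"] * 4 + ["JC+G"] * 4,
            "BIC": ["JC", "JC", "JC", "JC"] + ["JC+G"] * 4,
            "DT": ["JC"] * 4 + ["JC+G"] * 4})
        out = model_bias_tables(sel, "category")
        # base+I and base+I+G never recovered -> pooled away
        assert len(out["pooled_labels"]) == 2


class TestModelBias:
    @pytest.fixture()
    def selections(self):
        rng = np.random.default_rng(5)
        truths = np.repeat(["JC", "JC+I", "JC+G", "JC+I+G"], 25)
        rows = []
        for truth in truths:
            row = {"true_model": truth}
            for crit in CRITERIA:
                row[crit] = truth if rng.random() < 0.7 else "HKY"
            rows.append(row)
        return pd.DataFrame(rows)

    def test_counts_only_recovered_models_by_default(self, selections):
        out = model_bias_tables(selections, "category")
        counts = out["counts"]
        matched = sum((selections["hLRT"] == selections["true_model"]))
        assert counts.loc["hLRT"].sum() == matched

    def test_all_selections_mode(self, selections):
        out = model_bias_tables(selections, "category", recovered_only=False)
        assert (out["counts"].sum(axis=1) == len(selections)).all()

    def test_nparams_classification_has_11_possible_classes(self, selections):
        out = model_bias_tables(selections, "nparams")
        assert out["counts"].shape == (4, 11)


class TestRandomizedBlockAnova:
    def test_identical_treatments_give_zero_f(self):
        vals = pd.DataFrame({
            c: [50.0, 60.0, 70.0, 40.0, 55.0, 65.0] for c in CRITERIA})
        out = randomized_block_anova(vals)
        assert out["treatment"]["F"] == pytest.approx(0.0)
        assert out["treatment"]["p_value"] == pytest.approx(1.0)

    def test_matches_statsmodels_two_way_ols(self):
        rng = np.random.default_rng(7)
        b, t = 8, 4
        base = rng.normal(60, 10, size=(b, 1))
        effect = np.array([[0.0, 5.0, -3.0, 1.0]])
        x = base + effect + rng.normal(0, 2, size=(b, t))
        vals = pd.DataFrame(x, columns=list(CRITERIA))
        out = randomized_block_anova(vals)

        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        long = vals.reset_index().melt(id_vars="index", var_name="crit",
                                       value_name="y")
        fit = ols("y ~ C(index) + C(crit)", data=long).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert out["treatment"]["F"] == pytest.approx(
            table.loc["C(crit)", "F"], rel=1e-8)
        assert out["block"]["F"] == pytest.approx(
            table.loc["C(index)", "F"], rel=1e-8)
        assert out["treatment"]["p_value"] == pytest.approx(
            table.loc["C(crit)", "PR(>F)"], rel=1e-6)

    def test_lsd_flags_match_definition(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 5, size=(10, 4))
        x[:, 1] += 12.0
        vals = pd.DataFrame(x, columns=list(CRITERIA))
        out = randomized_block_anova(vals, alpha=0.05)
        from scipy.stats import t as t_dist
        mse = out["ms_error"]
        b = len(vals)
        tcrit = t_dist.ppf(0.975, (b - 1) * 3)
        for _, row in out["lsd"].iterrows():
            want = abs(row["mean_diff"]) > tcrit * np.sqrt(2 * mse / b)
            assert row["significant"] == want

    def test_missing_cells_rejected(self):
        vals = pd.DataFrame({c: [1.0, np.nan] for c in CRITERIA})
        with pytest.raises(ValueError):
            randomized_block_anova(vals)


class TestTidyTables:
    @pytest.fixture()
    def selections(self):
        return pd.DataFrame({
            "true_model": ["JC"] * 3 + ["HKY"] * 3,
            "hLRT": ["JC", "JC", "K80", "HKY", "HKY", "HKY"],
            "AIC": ["JC", "K80", "K80", "HKY", "TrN", "HKY"],
            "BIC": ["JC", "JC", "JC", "HKY", "HKY", "HKY"],
            "DT": ["JC", "JC", "JC", "HKY", "HKY", "HKY"]})

    def test_performance_table_values(self, selections):
        perf = performance_table(selections, "X")
        jc_bic = perf[(perf.true_model == "JC") & (perf.criterion == "BIC")]
        assert jc_bic.accuracy_pct.iloc[0] == pytest.approx(100.0)
        jc_aic = perf[(perf.true_model == "JC") & (perf.criterion == "AIC")]
        assert jc_aic.accuracy_pct.iloc[0] == pytest.approx(100.0 / 3)
        assert jc_aic.precision.iloc[0] == 2

    def test_dissimilarity_table_symmetry_in_pairs(self, selections):
        tab = dissimilarity_table(selections, "X", by_model=False)
        assert len(tab) == 6
        bic_dt = tab[tab.pair == "BIC-DT"].dissimilarity_pct.iloc[0]
        assert bic_dt == 0.0
        hlrt_aic = tab[tab.pair == "hLRT-AIC"].dissimilarity_pct.iloc[0]
        assert hlrt_aic == pytest.approx(100.0 * 2 / 6)
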