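"""Group-comparison battery: Kruskal-Wallis, Dunn, chi-square, proportions, factorial."""

import numpy as np
import pandas as pd
import pytest

from edrcomplex import (
    ContingencyTable,
    chi_square_independence,
    dunn_posthoc,
    kruskal_wallis,
    pairwise_proportion_ztests,
    twoway_factorial,
)
from edrcomplex.errors import InvalidArgumentError


class TestKruskalWallis:
    def test_closed_form_separated_groups(self):
        # ranks 1..9 in three blocks: mean ranks 2/5/8, H = 7.2 in closed form
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(values, groups)
        assert res.df == 2
        assert res.statistic == pytest.approx(7.2, abs=1e-10)
        assert res.extra["mean_ranks"] == {"a": 2.0, "b": 5.0, "c": 8.0}

    def test_identical_multisets_give_zero_h(self):
        values = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(values, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_invariance_under_monotone_transform(self, rng):
        values = rng.normal(size=60)
        groups = np.repeat(["a", "b", "c"], 20)
        h1 = kruskal_wallis(values, groups).statistic
        h2 = kruskal_wallis(np.exp(values), groups).statistic
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_type_i_error_near_nominal(self, rng):
        n_sims, rejections = 500, 0
        groups = np.repeat(["a", "b", "c"], 15)
        for _ in range(n_sims):
            if kruskal_wallis(rng.normal(size=45), groups).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_sims <= 0.065


class TestDunn:
    def test_identical_groups_give_z_zero(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        table = dunn_posthoc(values, groups)
        assert table["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_corrected"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_is_min_one_three_raw(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        table = dunn_posthoc(values, groups)
        assert len(table) == 3
        for _, row in table.iterrows():
            assert row["p_corrected"] == pytest.approx(min(1.0, 3 * row["p_raw"]))
            assert row["p_corrected"] >= row["p_raw"] - 1e-15

    def test_separated_cohort_pair_significant(self, rng):
        hits = 0
        for s in range(50):
            r = np.random.default_rng(s)
            uws = r.normal(0.97 - 0.15, 0.15, 42)
            mcs = r.normal(1.11, 0.15, 61)
            emcs = r.normal(1.10, 0.15, 99)
            values = np.concatenate([uws, mcs, emcs])
            groups = np.array(["UWS"] * 42 + ["MCS"] * 61 + ["EMCS"] * 99)
            table = dunn_posthoc(values, groups)
            row = table[table["pair"].str.contains("UWS") & table["pair"].str.contains("EMCS")]
            hits += int(row["p_corrected"].iloc[0] < 0.05)
        assert hits >= 48


class TestChiSquare:
    def test_perfect_independence(self):
        table = ContingencyTable(
            counts=[[10, 10], [10, 10]], row_labels=("x", "y"), col_labels=("a", "b")
        )
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        # Pearson X2 = sum (O-E)^2/E computed by hand for a 2x2 table
        counts = np.array([[12.0, 5.0], [8.0, 15.0]])
        table = ContingencyTable(counts=counts, row_labels=("p", "a"), col_labels=("l", "r"))
        res = chi_square_independence(table, method="pearson")
        n = counts.sum()
        expected = np.outer(counts.sum(1), counts.sum(0)) / n
        x2_hand = float(((counts - expected) ** 2 / expected).sum())
        assert res.statistic == pytest.approx(x2_hand, abs=1e-10)
        g_hand = float(2 * (counts * np.log(counts / expected)).sum())
        assert res.extra["variants"]["likelihood_ratio"]["statistic"] == pytest.approx(
            g_hand, abs=1e-10
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ContingencyTable(
                counts=[[0, 0], [3, 4]], row_labels=("p", "a"), col_labels=("l", "r")
            )

    def test_both_variants_reported(self):
        table = ContingencyTable.from_presence([9, 24, 52], [42, 61, 99])
        res = chi_square_independence(table)
        assert {"pearson", "likelihood_ratio"} <= set(res.extra["variants"])


class TestPairwiseProportions:
    def test_equal_proportions_share_subset(self):
        table = ContingencyTable.from_presence([20, 20], [50, 50], col_labels=("a", "b"))
        out = pairwise_proportion_ztests(table)
        assert out["z"].iloc[0] == pytest.approx(0.0)
        letters = out.attrs["subset_letters"]
        assert letters["a"] == letters["b"]

    def test_theta_frequency_row_subset_structure(self):
        # published theta-frequency counts: the two lower classes share a
        # subset, the emerged class stands apart
        table = ContingencyTable.from_presence([4, 14, 49], [42, 61, 99])
        out = pairwise_proportion_ztests(table)
        letters = out.attrs["subset_letters"]
        assert set(letters["UWS"]) & set(letters["MCS"])
        assert not set(letters["EMCS"]) & set(letters["UWS"])
        assert not set(letters["EMCS"]) & set(letters["MCS"])

    def test_subsets_invariant_to_column_order(self):
        t1 = ContingencyTable.from_presence([4, 14, 49], [42, 61, 99])
        t2 = ContingencyTable.from_presence(
            [49, 4, 14], [99, 42, 61], col_labels=("EMCS", "UWS", "MCS")
        )
        l1 = pairwise_proportion_ztests(t1).attrs["subset_letters"]
        l2 = pairwise_proportion_ztests(t2).attrs["subset_letters"]
        same1 = {(a, b): bool(set(l1[a]) & set(l1[b])) for a in l1 for b in l1}
        same2 = {(a, b): bool(set(l2[a]) & set(l2[b])) for a in l2 for b in l2}
        assert same1 == same2


class TestTwowayFactorial:
    @staticmethod
    def _balanced(rng, effect=0.0):
        levels_c = np.repeat(["UWS", "MCS", "EMCS"], 40)
        levels_e = np.tile(np.repeat(["traumatic", "anoxic"], 20), 3)
        y = rng.normal(size=120)
        y += effect * (levels_c == "EMCS")
        return y, levels_c, levels_e

    def test_balanced_type_ii_equals_type_iii(self, rng):
        y, c, e = self._balanced(rng, effect=0.4)
        res3 = twoway_factorial(y, c, e)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame({"apen": y, "consciousness": c, "etiology": e})
        fit2 = smf.ols("apen ~ C(consciousness) * C(etiology)", data=df).fit()
        t2 = anova_lm(fit2, typ=2)
        f2 = float(t2.loc["C(consciousness)", "F"])
        assert res3.extra["terms"]["consciousness"]["F"] == pytest.approx(f2, rel=1e-8)

    def test_reports_all_terms_and_posthocs(self, rng):
        y, c, e = self._balanced(rng, effect=0.5)
        res = twoway_factorial(y, c, e)
        assert set(res.extra["terms"]) == {"consciousness", "etiology", "interaction"}
        assert (res.post_hoc["p_corrected"] >= res.post_hoc["p_raw"] - 1e-15).all()

    def test_empty_cell_falls_back_to_type_ii(self, rng):
        y = rng.normal(size=30)
        c = np.array(["UWS"] * 10 + ["MCS"] * 10 + ["EMCS"] * 10)
        e = np.array(["traumatic"] * 10 + ["anoxic"] * 10 + ["anoxic"] * 10)
        with pytest.warns(UserWarning, match="empty factor cells"):
            res = twoway_factorial(y, c, e)
        assert res.extra["anova_type"] == 2

    def test_type_i_error_of_main_effect_near_nominal(self):
        n_sims, rejections_main, rejections_inter = 400, 0, 0
        c = np.repeat(["UWS", "MCS", "EMCS"], 40)
        e = np.tile(np.repeat(["t", "a"], 20), 3)
        for s in range(n_sims):
            r = np.random.default_rng(10_000 + s)
            res = twoway_factorial(r.normal(size=120), c, e)
            rejections_main += res.extra["terms"]["consciousness"]["p"] < 0.05
            rejections_inter += res.extra["terms"]["interaction"]["p"] < 0.05
        assert 0.03 <= rejections_main / n_sims <= 0.07
        assert 0.03 <= rejections_inter / n_sims <= 0.07
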