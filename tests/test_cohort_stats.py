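"""Rank factorial test, Dunn post hoc, design dispatch, PCA, paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lglpheno.cohort_stats import (compare_groups, dunn_posthoc,
                                   min_attainable_sign_rank_p,
                                   paired_tissue_compare, pca_summary,
                                   rank_tukey_posthoc, scheirer_ray_hare)


def srh_oracle(y, a, b):
    """Independent oracle: rank, then textbook two-way ANOVA sums of
    squares computed cell-by-cell, H = SS / (SS_total/(N-1))."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    r = stats.rankdata(y)
    n = len(r)
    cf = r.sum() ** 2 / n
    ss_total = (r ** 2).sum() - cf

    def ss_for(labels):
        return sum(r[labels == l].sum() ** 2 / (labels == l).sum()
                   for l in np.unique(labels)) - cf

    ss_a, ss_b = ss_for(a), ss_for(b)
    cells = np.char.add(a.astype(str), np.char.add("|", b.astype(str)))
    ss_cells = ss_for(cells)
    ms_total = ss_total / (n - 1)
    return (ss_a / ms_total, ss_b / ms_total,
            (ss_cells - ss_a - ss_b) / ms_total)


class TestScheirerRayHare:
    def test_hand_computed_2x2_example(self):
        """Eight untied values in a 2x2 design: H_A = 4.0833, H_B = 0.75,
        interaction 0 (hand rank-ANOVA arithmetic)."""
        y = [1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0, 8.0]
        a = ["a", "a", "a", "a", "b", "b", "b", "b"]
        b = ["x", "x", "y", "y", "x", "x", "y", "y"]
        res = scheirer_ray_hare(y, a, b)
        assert res.H_A == pytest.approx(4.083333, abs=1e-6)
        assert res.H_B == pytest.approx(0.75, abs=1e-6)
        assert res.H_interaction == pytest.approx(0.0, abs=1e-9)
        assert res.tie_correction == 1.0

    def test_single_level_factor_reduces_to_kruskal_wallis(self):
        """With factor B constant, H_A equals the tie-corrected
        Kruskal-Wallis H (scipy as the independent reference)."""
        rng = np.random.default_rng(3)
        y = np.round(rng.normal(size=30), 1)  # rounding forces ties
        a = np.repeat(["g1", "g2", "g3"], 10)
        res = scheirer_ray_hare(y, a, np.repeat("only", 30))
        kw = stats.kruskal(y[:10], y[10:20], y[20:])
        assert res.H_A == pytest.approx(kw.statistic, rel=1e-12)
        assert np.isnan(res.H_B)

    @pytest.mark.parametrize("rep", range(20))
    def test_matches_rank_anova_oracle(self, rep):
        rng = np.random.default_rng(100 + rep)
        ka, kb = rng.integers(2, 4, size=2)
        npc = int(rng.integers(2, 6))
        a = np.repeat([f"a{i}" for i in range(ka)], kb * npc)
        b = np.tile(np.repeat([f"b{i}" for i in range(kb)], npc), ka)
        y = rng.integers(0, 12, size=len(a)).astype(float)  # heavy ties
        res = scheirer_ray_hare(y, a, b)
        ha, hb, hab = srh_oracle(y, a, b)
        assert res.H_A == pytest.approx(ha, rel=1e-10)
        assert res.H_B == pytest.approx(hb, rel=1e-10)
        assert res.H_interaction == pytest.approx(hab, rel=1e-10, abs=1e-10)

    def test_no_ties_tie_correction_unity_and_additivity(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=24)
        a = np.repeat(["x", "y"], 12)
        b = np.tile(np.repeat(["u", "v", "w"], 4), 2)
        res = scheirer_ray_hare(y, a, b)
        assert res.tie_correction == 1.0
        # rank SS decomposition: effects cannot exceed the total
        assert (res.ss["A"] + res.ss["B"] + res.ss["interaction"]
                <= res.ss["total"] + 1e-9)

    def test_empty_cell_skips_interaction(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        a = ["a", "a", "a", "b", "b"]
        b = ["x", "x", "y", "x", "x"]  # cell (b, y) empty
        with pytest.warns(UserWarning, match="empty"):
            res = scheirer_ray_hare(y, a, b)
        assert np.isnan(res.H_interaction)
        assert np.isfinite(res.H_A)


class TestDunn:
    def test_identical_groups_z_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        grp = ["a"] * 3 + ["b"] * 3
        p = dunn_posthoc(vals, grp)
        assert p.loc["a", "b"] == pytest.approx(1.0)
        assert p.attrs["z"].loc["a", "b"] == pytest.approx(0.0)

    def test_textbook_three_group_example(self):
        """Hand-computed z for a 3x4 untied example:
        z_12 = 1.5689, z_13 = 2.2553, z_23 = 0.6864."""
        vals = [28, 33, 35, 38, 32, 29, 20, 18, 15, 30, 12, 24]
        grp = np.repeat(["g1", "g2", "g3"], 4)
        p = dunn_posthoc(vals, grp)
        z = p.attrs["z"]
        assert z.loc["g1", "g2"] == pytest.approx(1.568929, abs=1e-5)
        assert z.loc["g1", "g3"] == pytest.approx(2.255336, abs=1e-5)
        assert z.loc["g2", "g3"] == pytest.approx(0.686406, abs=1e-5)
        assert p.loc["g1", "g3"] == pytest.approx(0.024112, abs=1e-5)

    def test_z_antisymmetry(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=30)
        grp = np.repeat(["a", "b", "c"], 10)
        z = dunn_posthoc(vals, grp).attrs["z"]
        for i in z.index:
            for j in z.columns:
                assert z.loc[i, j] == pytest.approx(-z.loc[j, i])

    def test_bonferroni_never_below_unadjusted(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=30)
        grp = np.repeat(["a", "b", "c"], 10)
        raw = dunn_posthoc(vals, grp, adjust="none")
        bon = dunn_posthoc(vals, grp, adjust="bonferroni")
        assert ((bon >= raw - 1e-12) | bon.isna()).all().all()
        assert (bon.to_numpy() <= 1.0).all()

    def test_group_label_and_row_order_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=30)
        grp = np.repeat(["a", "b", "c"], 10)
        p1 = dunn_posthoc(vals, grp)
        order = rng.permutation(30)
        p2 = dunn_posthoc(vals[order], grp[order])
        relabel = {"a": "x1", "b": "x2", "c": "x3"}  # monotone relabeling
        p3 = dunn_posthoc(vals, [relabel[g] for g in grp])
        assert p1.loc["a", "b"] == pytest.approx(p2.loc["a", "b"])
        assert p1.loc["a", "b"] == pytest.approx(p3.loc["x1", "x2"])

    def test_rank_tukey_agrees_on_extreme_separation(self):
        vals = np.concatenate([np.arange(10), np.arange(100, 110)])
        grp = np.repeat(["lo", "hi"], 10)
        p = rank_tukey_posthoc(vals, grp)
        assert p.loc["lo", "hi"] < 0.01


class TestCompareGroups:
    def _df(self, rng, shift=0.0, n=20):
        return pd.DataFrame({
            "value": np.concatenate([rng.normal(0, 1, n),
                                     rng.normal(shift, 1, n)]),
            "group": np.repeat(["a", "b"], n)})

    def test_identical_groups_high_p(self):
        df = pd.DataFrame({"value": list(range(10)) * 2,
                           "group": ["a"] * 10 + ["b"] * 10})
        res = compare_groups(df, "value", "group", "two_independent")
        assert res.p > 0.9
        assert res.test == "mann_whitney_u"

    def test_mann_whitney_power_at_one_sd_shift(self):
        """Planted 1 SD location shift, n=50 per group: power > 0.9."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = self._df(rng, shift=1.0, n=50)
            hits += compare_groups(df, "value", "group",
                                   "two_independent").p < 0.05
        assert hits / reps > 0.9

    def test_kruskal_dispatch_with_posthoc(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "value": np.concatenate([rng.normal(0, 1, 15),
                                     rng.normal(0, 1, 15),
                                     rng.normal(3, 1, 15)]),
            "group": np.repeat(["a", "b", "c"], 15)})
        res = compare_groups(df, "value", "group", "k_independent")
        assert res.test == "kruskal_wallis"
        assert res.posthoc is not None
        assert res.posthoc.loc["a", "c"] < 0.05

    def test_factorial_dispatches_to_srh(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({
            "value": rng.normal(size=36),
            "group": np.repeat(["a", "b", "c"], 12),
            "marker": np.tile(np.repeat(["m1", "m2"], 6), 3)})
        res = compare_groups(df, "value", "group", "factorial",
                             factor_b="marker", posthoc="rank_tukey")
        assert res.test == "scheirer_ray_hare"
        assert "srh" in res.extra
        assert res.posthoc.attrs["method"] == "rank_tukey"

    def test_paired_design_on_identical_conditions(self):
        df = pd.DataFrame({
            "value": [1.0, 2, 3, 1, 2, 3], "cond": ["x"] * 3 + ["y"] * 3,
            "subject": ["s1", "s2", "s3"] * 2})
        res = compare_groups(df, "value", "cond", "two_paired",
                             subject_col="subject")
        assert res.p == 1.0

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            compare_groups(pd.DataFrame({"value": [1], "group": ["a"]}),
                           "value", "group", "anova")


class TestPCA:
    def test_perfectly_correlated_features_pc1_everything(self):
        x = np.arange(50.0)
        df = pd.DataFrame({"f1": x, "f2": 3 * x + 1})
        out = pca_summary(df)
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(100, 4)),
                          columns=["a", "b", "c", "d"])
        L = pca_summary(df)["loadings"].to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-10)

    def test_independent_features_spread_evenly(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(2000, 4)),
                          columns=["a", "b", "c", "d"])
        ratio = pca_summary(df)["explained_variance_ratio"]
        assert ratio.max() < 0.35

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"a": rng.normal(size=30),
                           "b": rng.normal(size=30),
                           "c": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            out = pca_summary(df)
        assert out["dropped"] == ["c"]


class TestPairedTissue:
    def _tables(self, diffs):
        blood = pd.DataFrame({"donor_id": [f"d{i}" for i in range(len(diffs))],
                              "pct": [10.0] * len(diffs)})
        muscle = blood.copy()
        muscle["pct"] = blood["pct"] + diffs
        return blood, muscle

    def test_three_concordant_pairs_hit_exact_floor(self):
        """n=3, all muscle > blood: exact one-tailed p = 1/8 = 0.125,
        annotated as the minimum attainable."""
        blood, muscle = self._tables([5.0, 3.0, 7.0])
        out = paired_tissue_compare(blood, muscle)
        row = out.iloc[0]
        assert row["p"] == pytest.approx(0.125)
        assert row["min_attainable_p"] == pytest.approx(0.125)
        assert row["at_floor"]

    def test_zero_differences_p_one(self):
        blood, muscle = self._tables([0.0, 0.0, 0.0])
        out = paired_tissue_compare(blood, muscle)
        assert out.iloc[0]["p"] == 1.0
        assert out.iloc[0]["median_diff"] == 0.0

    def test_min_attainable_enumeration(self):
        # 2^n equally likely sign patterns; one is all-positive
        for n in (1, 3, 5, 8):
            assert min_attainable_sign_rank_p(n) == pytest.approx(0.5 ** n)

    def test_no_matched_pairs_rejected(self):
        blood = pd.DataFrame({"donor_id": ["a"], "pct": [1.0]})
        muscle = pd.DataFrame({"donor_id": ["b"], "pct": [1.0]})
        with pytest.raises(ValueError, match="matched"):
            paired_tissue_compare(blood, muscle)
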