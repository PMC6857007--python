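"""Joint methylation-expression analyses: the qualifying-gene table, rank
correlations, the slope-interaction GLM, enrichment odds ratios, paired
shifts, and the X/A distribution contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import aphimeth as am
from aphimeth.integrate import (distribution_contrast, dm_de_overlap_test,
                                enrichment_contrasts, fc_correlation,
                                interaction_glm, joint_table,
                                paired_shift_test)
from aphimeth.model import ValidationError


def make_joint(rng, n=400, slope_a=0.2, slope_x=0.2, frac_x=0.3, sigma=0.5):
    on_x = rng.random(n) < frac_x
    fc_meth = rng.normal(0, 1, n)
    slope = np.where(on_x, slope_x, slope_a)
    fc_expr = slope * fc_meth + rng.normal(0, sigma, n)
    return pd.DataFrame({"FC_Meth": fc_meth, "FC_Expr": fc_expr,
                         "linkage": np.where(on_x, "X", "A")})


class TestJointTable:
    def _inputs(self):
        gm = pd.DataFrame({"level_F": [0.9, 30.0, 50.0],
                           "level_M": [0.9, 40.0, 0.5]},
                          index=["g1", "g2", "g3"])
        gm.index.name = "gene_id"
        expr = pd.DataFrame({"mean_F": [10.0, 0.0, 5.0],
                             "mean_M": [12.0, 10.0, 5.0],
                             "bias_class": ["UB", "MB", "UB"],
                             "q": [0.5, 0.01, 0.9]},
                            index=["g1", "g2", "g3"])
        asg = pd.DataFrame({"scaffold": ["s"], "length": [30_000],
                            "linkage": ["A"]})
        return gm, expr, asg

    def test_methylation_floor_excludes(self):
        gm, expr, asg = self._inputs()
        jt = joint_table(gm, expr, asg)
        assert "g1" not in jt.index        # 0.9% in both sexes
        assert {"g2", "g3"} <= set(jt.index)

    def test_fc_formula_with_offset(self):
        gm, expr, asg = self._inputs()
        jt = joint_table(gm, expr, asg)
        assert jt.loc["g2", "FC_Expr"] == pytest.approx(
            np.log2(10.01 / 0.01), abs=1e-9)

    def test_is_pure_function_of_inputs(self):
        gm, expr, asg = self._inputs()
        a = joint_table(gm, expr, asg)
        b = joint_table(gm, expr, asg)
        pd.testing.assert_frame_equal(a, b)


class TestFcCorrelation:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"FC_Meth": [1.0, 2, 3, 4],
                           "FC_Expr": [0.1, 0.5, 0.7, 2.0],
                           "linkage": "A"})
        assert fc_correlation(df)["rho"] == pytest.approx(1.0)
        df["FC_Expr"] = -df["FC_Expr"]
        assert fc_correlation(df)["rho"] == pytest.approx(-1.0)

    def test_constant_flagged_undefined(self):
        df = pd.DataFrame({"FC_Meth": [1.0, 1.0, 1.0],
                           "FC_Expr": [0.1, 0.5, 0.7], "linkage": "A"})
        assert fc_correlation(df)["undefined"]

    def test_rank_invariance_under_monotone_transform(self, rng):
        df = make_joint(rng, 200)
        r1 = fc_correlation(df)["rho"]
        df2 = df.copy()
        df2["FC_Meth"] = np.exp(df2["FC_Meth"])           # monotone
        df2["FC_Expr"] = df2["FC_Expr"] ** 3              # monotone
        assert fc_correlation(df2)["rho"] == pytest.approx(r1, abs=1e-12)


class TestInteractionGlm:
    def test_duplicated_groups_give_no_interaction(self, rng):
        a = make_joint(rng, 200, frac_x=0.0)
        x = a.copy()
        x["linkage"] = "X"
        res = interaction_glm(pd.concat([a, x], ignore_index=True))
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_single_linkage_errors(self, rng):
        df = make_joint(rng, 50, frac_x=0.0)
        with pytest.raises(ValidationError):
            interaction_glm(df)

    def test_null_p_uniform_over_replicates(self):
        rng = np.random.default_rng(10)
        ps = [interaction_glm(make_joint(rng, 500))["p"]
              for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_slope_difference(self):
        rng = np.random.default_rng(11)
        hits = sum(interaction_glm(make_joint(rng, 3000, slope_a=0.05,
                                              slope_x=0.5))["p"] < 0.001
                   for _ in range(20))
        assert hits >= 19

    def test_recovers_generating_slopes(self):
        rng = np.random.default_rng(12)
        res = interaction_glm(make_joint(rng, 6000, slope_a=0.1,
                                         slope_x=0.4))
        assert res["slopes"]["A"] == pytest.approx(0.1, abs=0.05)
        assert res["slopes"]["X"] == pytest.approx(0.4, abs=0.05)
        assert res["df"][0] == 1 and res["df"][1] == 6000 - 4


class TestEnrichment:
    def test_flat_table_or_one(self):
        df = pd.DataFrame({
            "linkage": ["X"] * 100 + ["A"] * 100,
            "de_class": (["MB"] * 10 + ["UB"] * 90) * 2})
        out = enrichment_contrasts(df).set_index("class")
        assert out.loc["MB", "odds_ratio"] == pytest.approx(1.0)
        assert out.loc["MB", "chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_cross_product_oracle(self):
        df = pd.DataFrame({
            "linkage": ["X"] * 100 + ["A"] * 100,
            "de_class": ["MB"] * 30 + ["UB"] * 70 + ["MB"] * 10 +
                        ["UB"] * 90})
        out = enrichment_contrasts(df).set_index("class")
        assert out.loc["MB", "odds_ratio"] == pytest.approx(
            (30 * 90) / (70 * 10))

    def test_engineered_x_enrichment_detected(self, rng):
        hits = 0
        for _ in range(20):
            n = 2000
            on_x = rng.random(n) < 0.25
            p_mbp = np.where(on_x, 0.10, 0.03)
            cls = np.where(rng.random(n) < p_mbp, "MB+", "UB")
            df = pd.DataFrame({"linkage": np.where(on_x, "X", "A"),
                               "de_class": cls})
            out = enrichment_contrasts(df).set_index("class")
            hits += (out.loc["MB+", "odds_ratio"] > 1 and
                     out.loc["MB+", "p"] < 0.05)
        assert hits >= 19

    def test_dm_de_overlap_chi2(self, rng):
        n = 2000
        dm = rng.random(n) < 0.2
        p_de = np.where(dm, 0.5, 0.2)
        de = rng.random(n) < p_de
        df = pd.DataFrame({"dm_class": np.where(dm, "MBm", "UB"),
                           "de_class": np.where(de, "MB", "UB")})
        res = dm_de_overlap_test(df)
        assert res["p"] < 0.001 and res["chi2"] > 0


class TestPairedShift:
    def test_all_zero_differences_flagged(self):
        res = paired_shift_test(np.ones(10), np.ones(10))
        assert res["undefined"] and res["n_nonzero"] == 0

    def test_exact_small_sample_one_sided(self):
        f = np.ones(5)
        m = np.array([2.0, 3, 4, 5, 6])
        res = paired_shift_test(f, m, alternative="greater")
        assert res["p"] == pytest.approx(1 / 32)

    def test_opposite_directions_on_x_and_autosomes(self, small_data,
                                                    bs_groups):
        gm = am.gene_methylation_levels(small_data["counts"],
                                        small_data["genes"], bs_groups)
        truth = small_data["truth"].genes.set_index("gene_id")
        gm = gm.join(truth[["linkage", "is_dm"]])
        dm_gm = gm[gm["is_dm"] & gm["level_F"].notna()]
        a = dm_gm[dm_gm["linkage"] == "A"]
        x = dm_gm[dm_gm["linkage"] == "X"]
        res_a = paired_shift_test(a["level_F"], a["level_M"])
        res_x = paired_shift_test(x["level_F"], x["level_M"])
        assert res_a["median_shift"] < 0 < res_x["median_shift"]


class TestDistributionContrast:
    def test_identical_samples_not_significant(self, rng):
        x = rng.beta(2, 5, 300)
        res = distribution_contrast(x, x.copy())
        assert res["p"] >= 0.25   # scipy caps the interpolated p at 0.25

    def test_different_shapes_detected(self, rng):
        res = distribution_contrast(rng.beta(1, 9, 500),
                                    rng.beta(5, 5, 500))
        assert res["p"] <= 0.001  # scipy floors the interpolated p at 0.001

    def test_invariance_under_common_monotone_transform(self, rng):
        x, a = rng.beta(2, 2, 100), rng.beta(3, 1, 100)
        r1 = distribution_contrast(x, a)["statistic"]
        r2 = distribution_contrast(np.log(x + 1), np.log(a + 1))["statistic"]
        assert r1 == pytest.approx(r2, abs=1e-9)
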