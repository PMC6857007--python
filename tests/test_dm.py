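"""Differential methylation: filters, the logistic LRT and its G-statistic
identity, bias classes, the sex-balanced pair null, and methylation PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import aphimeth as am
from aphimeth.dm import (calibrate_dm_threshold, classify_dm,
                         dm_gene_test, dm_logistic_test,
                         enumerate_pair_groupings, filter_dm_units,
                         logistic_lrt, methylation_pca,
                         rank_sum_by_sex_vs_mixed, dm_site_gene_overlap,
                         site_level_matrix)
from aphimeth.model import GeneModel, ValidationError
from conftest import make_site_counts


def g_statistic(table):
    """Independent oracle: 2 * sum O ln(O/E) over a 2x2 table."""
    O = np.asarray(table, dtype=float)
    E = np.outer(O.sum(1), O.sum(0)) / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    return 2.0 * terms.sum()


class TestFilters:
    def test_low_coverage_site_dropped(self):
        cov = pd.DataFrame({"a": [4, 10], "b": [30, 30]})
        keep = filter_dm_units(cov, 5, 0.0)   # no top drop
        assert not keep[0]

    def test_extreme_coverage_site_dropped(self, rng):
        cov = pd.DataFrame({"a": np.r_[np.full(999, 30), 5000],
                            "b": np.full(1000, 30)})
        keep = filter_dm_units(cov, 5, 0.001)
        assert keep[:999].all() and not keep[999]

    def test_gene_below_20_reads_dropped(self):
        cov = pd.DataFrame({"a": [19, 25], "b": [40, 40]})
        keep = filter_dm_units(cov, 20, 0.0)
        assert not keep[0] and keep[1]


class TestLogisticLRT:
    def test_identical_groups_give_null(self):
        lrt, p, diff = logistic_lrt(50, 50, 50, 50)
        assert lrt == 0.0 and p == 1.0 and diff == 0.0

    def test_worked_example_equals_g_test(self):
        lrt, p, diff = logistic_lrt(90, 10, 10, 90)
        assert lrt == pytest.approx(g_statistic([[90, 10], [10, 90]]),
                                    abs=1e-9)
        assert lrt == pytest.approx(147.2257, abs=0.01)
        assert diff == pytest.approx(-80.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    def test_lrt_equals_g_statistic_property(self, mF, uF, mM, uM):
        if mF + uF == 0 or mM + uM == 0:
            return
        lrt, _, _ = logistic_lrt(mF, uF, mM, uM)
        assert abs(float(lrt) - g_statistic([[mF, uF], [mM, uM]])) < 1e-6

    def test_matches_iterative_glm_fit(self, rng):
        # closed form vs statsmodels binomial GLM over replicate structures
        import statsmodels.api as sm
        for _ in range(10):
            mF = rng.integers(1, 60, 3)
            uF = rng.integers(1, 60, 3)
            mM = rng.integers(1, 60, 3)
            uM = rng.integers(1, 60, 3)
            lrt, _, _ = logistic_lrt(mF.sum(), uF.sum(), mM.sum(), uM.sum())
            y = np.c_[np.r_[mF, mM], np.r_[uF, uM]]
            X = sm.add_constant(np.r_[np.zeros(3), np.ones(3)])
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, np.ones((6, 1)),
                          family=sm.families.Binomial()).fit()
            assert abs(float(lrt) - 2 * (full.llf - null.llf)) < 1e-6

    def test_null_replicates_give_uniform_p(self, rng):
        n = 10_000
        pi = rng.uniform(0.2, 0.8, n)
        nF = rng.poisson(30, (n, 3))
        mF = rng.binomial(nF, pi[:, None])
        nM = rng.poisson(30, (n, 3))
        mM = rng.binomial(nM, pi[:, None])
        _, p, _ = logistic_lrt(mF.sum(1), (nF - mF).sum(1),
                               mM.sum(1), (nM - mM).sum(1))
        assert 0.04 <= np.mean(p < 0.05) <= 0.06

    def test_zero_coverage_group_flagged(self):
        lrt, p, diff = logistic_lrt(0, 0, 5, 5)
        assert np.isnan(p) and np.isnan(diff)


class TestClassification:
    def _rec(self, diff, q):
        return pd.DataFrame({"unit_id": range(len(diff)), "diff": diff,
                             "p": q, "level_F": 0, "level_M": 0})

    def test_threshold_semantics_site_vs_gene(self):
        rec = pd.DataFrame({"unit_id": [1], "diff": [12.0], "p": [1e-6],
                            "level_F": [10.0], "level_M": [22.0]})
        site = classify_dm(rec, min_diff=15, fdr=0.05)
        gene = classify_dm(rec, min_diff=10, fdr=0.05)
        assert site["bias_class"].iloc[0] == "UB"
        assert gene["bias_class"].iloc[0] == "MBm"

    def test_direction_and_significance(self):
        rec = pd.DataFrame({"unit_id": [1, 2, 3],
                            "diff": [20.0, -40.0, 20.0],
                            "p": [1e-4, 0.9, 1e-4]})
        out = classify_dm(rec, min_diff=15, fdr=0.05)
        assert list(out["bias_class"]) == ["MBm", "UB", "MBm"]
        assert (out.loc[out.bias_class == "MBm", "diff"] > 0).all()


class TestPairGroupings:
    def test_printed_counts_for_3v3(self):
        gps = enumerate_pair_groupings(["F1", "F2", "F3"],
                                       ["M1", "M2", "M3"])
        kinds = pd.Series([g.kind for g in gps]).value_counts()
        assert kinds["by_sex"] == 9
        assert kinds["mixed"] == 18

    def test_2v2_counts_match_exhaustive_enumeration(self):
        gps = enumerate_pair_groupings(["F1", "F2"], ["M1", "M2"])
        kinds = pd.Series([g.kind for g in gps]).value_counts()
        # oracle: enumerate all sex-balanced 2v2 splits of 2F+2M by brute
        # force, collapsing group swaps
        seen = set()
        for fa, ma in [("F1", "M1"), ("F1", "M2"), ("F2", "M1"),
                       ("F2", "M2")]:
            fb = "F2" if fa == "F1" else "F1"
            mb = "M2" if ma == "M1" else "M1"
            key = frozenset([frozenset([fa, ma]), frozenset([fb, mb])])
            seen.add(key)
        assert kinds["mixed"] == len(seen) == 2
        assert kinds["by_sex"] == 1

    def test_mixed_groups_are_sex_balanced_and_disjoint(self):
        for g in enumerate_pair_groupings(["F1", "F2", "F3"],
                                          ["M1", "M2", "M3"]):
            if g.kind == "mixed":
                for grp in (g.group_a, g.group_b):
                    assert sum(s.startswith("F") for s in grp) == 1
                    assert sum(s.startswith("M") for s in grp) == 1
                assert not set(g.group_a) & set(g.group_b)

    def test_too_few_replicates_error(self):
        with pytest.raises(ValidationError):
            enumerate_pair_groupings(["F1"], ["M1", "M2"])


class TestCalibration:
    def test_complete_separation_gives_w_162(self):
        calib = pd.DataFrame({
            "grouping_id": [f"g{i}" for i in range(27)],
            "kind": ["by_sex"] * 9 + ["mixed"] * 18,
            "threshold": 15.0,
            "n_dm": list(range(100, 109)) + list(range(1, 19))})
        res = rank_sum_by_sex_vs_mixed(calib, 15)
        assert res["W"] == 162.0
        assert res["complete_separation"]

    def test_small_case_w_4(self):
        calib = pd.DataFrame({"grouping_id": list("abcd"),
                              "kind": ["by_sex"] * 2 + ["mixed"] * 2,
                              "threshold": 15.0, "n_dm": [3, 4, 1, 2]})
        assert rank_sum_by_sex_vs_mixed(calib, 15)["W"] == 4.0

    def test_exchangeable_counts_center_at_half_product(self, rng):
        # E[U] = n1 n2 / 2 when by-sex and mixed counts are exchangeable
        ws = []
        for _ in range(200):
            vals = rng.poisson(20, 27)
            calib = pd.DataFrame({
                "grouping_id": [f"g{i}" for i in range(27)],
                "kind": ["by_sex"] * 9 + ["mixed"] * 18,
                "threshold": 15.0, "n_dm": vals})
            ws.append(rank_sum_by_sex_vs_mixed(calib, 15)["W"])
        assert abs(np.mean(ws) - 81.0) < 5.0

    def test_sex_effect_separates_on_synthetic_data(self, small_data):
        cpg = small_data["counts"].in_context("CpG")
        gps = enumerate_pair_groupings(["F1", "F2", "F3"],
                                       ["M1", "M2", "M3"])
        calib = calibrate_dm_threshold(cpg, gps, thresholds=[15])
        res = rank_sum_by_sex_vs_mixed(calib, 15)
        assert res["complete_separation"]
        assert res["W"] == 162.0


class TestPCA:
    def test_duplicated_samples_coincide(self):
        X = pd.DataFrame([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9],
                          [0.8, 0.2, 0.4]], index=["a", "a2", "b"])
        res = methylation_pca(X)
        s = res["scores"]
        assert np.allclose(s.loc["a"], s.loc["a2"])

    def test_variance_fractions_sum_to_one(self, rng):
        X = pd.DataFrame(rng.random((5, 40)))
        res = methylation_pca(X)
        assert res["variance_fraction"].sum() == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            methylation_pca(pd.DataFrame([[0.1, 0.2]]))

    def test_pc1_separates_sexes_on_synthetic_data(self, small_data):
        err = am.estimate_conversion_error(small_data["control"])
        calls = am.call_methylated_sites(small_data["counts"], err.lam)
        keys = calls.loc[calls["call"],
                         ["scaffold", "pos", "strand"]].drop_duplicates()
        mat = site_level_matrix(small_data["counts"].in_context("CpG"), keys)
        res = methylation_pca(mat)
        pc1 = res["scores"]["PC1"]
        f = pc1[["F1", "F2", "F3"]].to_numpy()
        m = pc1[["M1", "M2", "M3"]].to_numpy()
        # complete separation of the sexes along PC1
        assert (f.max() < m.min()) or (m.max() < f.min())


class TestDmSiteGeneOverlap:
    def _genes(self):
        return [GeneModel("g1", "s", "+", 5000, 9000, exons=[(5000, 9000)])]

    def test_flank_rule(self):
        dm_sites = pd.DataFrame({"scaffold": ["s", "s"],
                                 "pos": [4501, 3501]})   # 500 bp, 1500 bp up
        res = dm_site_gene_overlap(dm_sites, self._genes(), flank=1000)
        assert res["per_gene_counts"].get("g1") == 1
        assert res["genic_fraction"] == pytest.approx(0.5)

    def test_site_in_two_overlapping_flanks_counts_twice(self):
        genes = self._genes() + [GeneModel("g2", "s", "+", 9500, 12000,
                                           exons=[(9500, 12000)])]
        dm_sites = pd.DataFrame({"scaffold": ["s"], "pos": [9200]})
        res = dm_site_gene_overlap(dm_sites, genes, flank=1000)
        assert res["per_gene_counts"] == {"g1": 1, "g2": 1}
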