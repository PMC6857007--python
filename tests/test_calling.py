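"""Methylation calling: context summaries, the control-calibrated binomial
caller, feature aggregation, metagene binning and expression strata."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aphimeth as am
from aphimeth.calling import (aggregate_feature_methylation, bh_adjust,
                              binomial_site_pvalues, call_methylated_sites,
                              context_methylation_summary,
                              estimate_conversion_error, metagene_profile,
                              methylation_bin,
                              methylation_expression_strata)
from aphimeth.model import GeneModel, ValidationError
from conftest import make_site_counts


class TestContextSummary:
    def test_all_unmethylated_gives_zero(self):
        sc = make_site_counts(
            [("s", 1, "+", "CpG", {"a": (0, 5)}),
             ("s", 2, "+", "CHH", {"a": (0, 9)})], ["a"])
        out = context_methylation_summary(sc)
        assert out.loc["CpG", "a"] == 0.0
        assert out.loc["CHH", "a"] == 0.0

    def test_pooled_is_read_weighted(self):
        sc = make_site_counts(
            [("s", 1, "+", "CpG", {"a": (7, 3)}),
             ("s", 2, "+", "CpG", {"a": (3, 7)})], ["a"])
        out = context_methylation_summary(sc, pooled=True)
        assert out.loc["CpG", "pooled"] == pytest.approx(0.5)

    def test_zero_coverage_context_flagged_nan(self):
        sc = make_site_counts([("s", 1, "+", "CpG", {"a": (1, 1)})], ["a"])
        out = context_methylation_summary(sc)
        assert np.isnan(out.loc["CHG", "a"])

    def test_cpg_dominates_on_synthetic_genome(self, small_data, small_cfg):
        # only CpG exceeds the conversion-error floor
        out = context_methylation_summary(small_data["counts"], pooled=True)
        lam = small_cfg.conversion_error_lambda
        assert out.loc["CpG", "pooled"] > 10 * lam
        assert out.loc["CHG", "pooled"] == pytest.approx(lam, rel=0.5)
        assert out.loc["CHH", "pooled"] == pytest.approx(lam, rel=0.5)


class TestConversionError:
    def test_worked_example(self):
        sc = make_site_counts([("c", 1, "+", "CpG", {"a": (45, 9955)})],
                              ["a"])
        err = estimate_conversion_error(sc)
        assert err.lam == pytest.approx(0.0045)

    def test_all_zero_m_gives_zero(self):
        sc = make_site_counts([("c", 1, "+", "CpG", {"a": (0, 100)})], ["a"])
        assert estimate_conversion_error(sc).lam == 0.0

    def test_zero_coverage_errors(self):
        sc = make_site_counts([("c", 1, "+", "CpG", {"a": (0, 0)})], ["a"])
        with pytest.raises(ValidationError):
            estimate_conversion_error(sc)

    def test_per_sample_rates_match_config(self, small_data, small_cfg):
        err = estimate_conversion_error(small_data["control"])
        lam = small_cfg.conversion_error_lambda
        for s, v in err.per_sample_lambdas.items():
            t = int(small_data["control"].coverage(s).sum())
            se = np.sqrt(lam * (1 - lam) / t)
            assert abs(v - lam) < 3.5 * se, s


class TestBinomialCaller:
    @pytest.mark.parametrize("m,u,lam,expected", [
        (0, 20, 0.0045, 1.0),                       # tail is whole support
        (1, 19, 0.0045, 1 - (1 - 0.0045) ** 20),    # closed-form complement
        (10, 0, 0.0045, 0.0045 ** 10),              # exact tail = lam^n
    ])
    def test_tail_probabilities(self, m, u, lam, expected):
        p = binomial_site_pvalues(np.array([m]), np.array([m + u]), lam)
        assert p[0] == pytest.approx(expected, rel=1e-9)

    def test_lambda_zero_limit(self):
        p = binomial_site_pvalues(np.array([0, 1]), np.array([5, 5]), 0.0)
        assert p.tolist() == [1.0, 0.0]

    def test_coverage_filter_applies_to_all_samples(self):
        sc = make_site_counts(
            [("s", 1, "+", "CpG", {"a": (3, 1), "b": (9, 1)}),
             ("s", 2, "+", "CpG", {"a": (5, 0), "b": (6, 0)})], ["a", "b"])
        calls = call_methylated_sites(sc, 0.0045)
        assert set(calls["pos"]) == {2}           # site 1 has coverage 4 in a

    def test_zero_fdr_limit_and_call_implies_methylated_reads(self,
                                                             small_data):
        err = estimate_conversion_error(small_data["control"])
        calls = call_methylated_sites(small_data["counts"], err.lam)
        # q >= 0 always, so thresholding at fdr = 0 calls nothing
        assert (calls["q"] < 0).sum() == 0
        # a called site must have at least one methylated read
        assert (calls.loc[calls["call"], "m"] >= 1).all()

    def test_control_genome_call_fraction_below_fdr(self, small_data):
        err = estimate_conversion_error(small_data["control"])
        calls = call_methylated_sites(small_data["control"], err.lam)
        assert calls["call"].mean() <= 0.05

    def test_bh_qvalues_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestFeatureAggregation:
    @pytest.fixture
    def one_gene(self):
        return [GeneModel("g1", "s", "+", 100, 400,
                          exons=[(100, 200), (300, 400)],
                          cds=[(150, 200), (300, 350)],
                          utr5=[(100, 150)], utr3=[(350, 400)])]

    def test_pooled_gene_level(self, one_gene):
        sc = make_site_counts(
            [("s", 150, "+", "CpG", {"a": (5, 5)}),
             ("s", 350, "+", "CpG", {"a": (2, 8)})], ["a"])
        out = aggregate_feature_methylation(sc, one_gene, classes=("gene",))
        assert out.loc[out.feature_id == "g1", "level"].iloc[0] == \
            pytest.approx(0.35)

    def test_uncovered_feature_flagged_undefined(self, one_gene):
        sc = make_site_counts([("s", 150, "+", "CpG", {"a": (0, 0)})], ["a"])
        out = aggregate_feature_methylation(sc, one_gene, classes=("gene",))
        assert bool(out["undefined"].iloc[0])

    def test_intergenic_complement(self, one_gene):
        sc = make_site_counts(
            [("s", 150, "+", "CpG", {"a": (1, 0)}),
             ("s", 900, "+", "CpG", {"a": (1, 1)})], ["a"])
        out = aggregate_feature_methylation(sc, one_gene,
                                            classes=("gene", "intergenic"))
        inter = out[out.feature_class == "intergenic"].iloc[0]
        assert inter.pooled_t == 2 and inter.pooled_m == 1

    def test_intron_vs_exon_partition(self, one_gene):
        sc = make_site_counts(
            [("s", 150, "+", "CpG", {"a": (1, 0)}),    # exon 1
             ("s", 250, "+", "CpG", {"a": (1, 0)}),    # intron
             ("s", 320, "+", "CpG", {"a": (1, 0)})], ["a"])  # exon 2
        out = aggregate_feature_methylation(sc, one_gene,
                                            classes=("exon", "intron"))
        exon = out[(out.feature_class == "exon")].iloc[0]
        intron = out[(out.feature_class == "intron")].iloc[0]
        assert exon.pooled_t == 2 and intron.pooled_t == 1

    def test_pooled_level_equals_coverage_weighted_mean(self, one_gene):
        # algebraic identity: pooled m/t == sum_s t_s * (m_s/t_s) / sum_s t_s
        sc = make_site_counts(
            [("s", 150, "+", "CpG", {"a": (5, 5), "b": (1, 9)}),
             ("s", 350, "+", "CpG", {"a": (2, 8), "b": (4, 6)})], ["a", "b"])
        pooled = aggregate_feature_methylation(sc, one_gene,
                                               classes=("gene",))
        per = {s: aggregate_feature_methylation(sc, one_gene, samples=[s],
                                                classes=("gene",))
               for s in "ab"}
        t = {s: per[s]["pooled_t"].iloc[0] for s in "ab"}
        lv = {s: per[s]["level"].iloc[0] for s in "ab"}
        weighted = sum(t[s] * lv[s] for s in "ab") / sum(t.values())
        assert pooled["level"].iloc[0] == pytest.approx(weighted)

    def test_exonic_share_dominates_intergenic_on_synthetic(self,
                                                            small_data):
        out = aggregate_feature_methylation(small_data["counts"],
                                            small_data["genes"])
        by_class = out.groupby("feature_class")[["pooled_m"]].sum()
        assert by_class.loc["exon", "pooled_m"] > \
            2 * by_class.loc["intergenic", "pooled_m"]


class TestMetagene:
    def _gene(self, strand="+"):
        return [GeneModel("g", "s", strand, 2000, 8000,
                          exons=[(2000, 8000)])]

    def test_uniform_sites_give_flat_body(self, rng):
        pos = rng.integers(2000, 8000, 10_000) + 1
        df = pd.DataFrame({"scaffold": "s", "pos": pos})
        prof = metagene_profile(df, self._gene())
        body = prof.covered[prof.body_slice].astype(float)
        exp = body.sum() / len(body)
        chi2 = ((body - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=len(body) - 1) > 0.01

    def test_constructed_3prime_mass_lands_in_last_bins(self, rng):
        pos = rng.integers(7400, 8000, 500) + 1          # last 10% of body
        df = pd.DataFrame({"scaffold": "s", "pos": pos})
        prof = metagene_profile(df, self._gene(),
                                methylated_mask=np.ones(500, bool))
        body = prof.methylated[prof.body_slice]
        assert body[-6:].sum() >= 0.95 * body.sum()

    def test_minus_strand_site_near_genomic_start_maps_to_tes(self):
        df = pd.DataFrame({"scaffold": ["s"], "pos": [2101]})
        prof = metagene_profile(df, self._gene("-"))
        body = prof.covered[prof.body_slice]
        assert body[-2:].sum() == 1 and body[:30].sum() == 0

    def test_short_genes_skipped_with_count(self):
        genes = [GeneModel("tiny", "s", "+", 0, 30, exons=[(0, 30)])]
        df = pd.DataFrame({"scaffold": ["s"], "pos": [10]})
        prof = metagene_profile(df, genes)
        assert prof.n_genes_skipped == 1 and prof.n_genes_used == 0

    def test_bin_counts_sum_to_total_in_range(self, rng):
        pos = rng.integers(1000, 9000, 2000) + 1
        df = pd.DataFrame({"scaffold": "s", "pos": pos})
        prof = metagene_profile(df, self._gene())
        in_range = ((pos - 1 >= 1000) & (pos - 1 < 9000)).sum()
        assert prof.covered.sum() == in_range


class TestExpressionStrata:
    def test_boundary_gene_at_one_percent_is_methylated_bin(self):
        assert methylation_bin(np.array([1.0]))[0] == "[1,25)"
        assert methylation_bin(np.array([0.99]))[0] == "[0,1)"
        assert methylation_bin(np.array([100.0]))[0] == "[75,100]"

    def test_coupling_raises_expression_of_methylated_genes(self, rng):
        n = 2000
        level = np.where(rng.random(n) < 0.5, 0.3,
                         rng.uniform(5, 80, n))
        fpkm = np.exp(rng.normal(2 + 0.02 * level, 0.5))
        res = methylation_expression_strata(pd.Series(level),
                                            pd.Series(fpkm))
        assert res["unmeth_vs_meth_p"] < 0.01
        assert res["trend_rho"] > 0

    def test_no_coupling_shows_no_trend(self, rng):
        n = 2000
        level = np.where(rng.random(n) < 0.5, 0.3, rng.uniform(5, 80, n))
        fpkm = np.exp(rng.normal(2, 0.5, n))
        res = methylation_expression_strata(pd.Series(level),
                                            pd.Series(fpkm))
        assert res["unmeth_vs_meth_p"] > 0.01
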