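"""The NB allelic-imbalance machinery: aggregation, normalization,
dispersion, exact tests, FDR and the full contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from asekit import asetest, synth
from tests.asetest_helpers import make_matrix
from asekit.asetest import (ASEModel, ContrastDesign, CountMatrix, aggregate,
                            bh_fdr, compare_sexes, estimate_dispersion,
                            filter_exclusive, fisher_pipeline, fisher_snp_test,
                            nb_exact_test, replicate_titration, run_contrast,
                            size_factors)
from asekit.types import GeneModel, GenomicInterval


def sim(seed=201, **kw):
    kw.setdefault("n_genes", 300)
    cfg = synth.SimulationConfig(seed=seed, **kw)
    ann = synth.gen_annotation(cfg)
    truth = synth.gen_truth(cfg)
    table = synth.gen_counts(ann, truth, cfg)
    return cfg, ann, truth, table


class TestAggregate:
    def test_gene_level_sums_member_snps(self, make_count_table):
        table = make_count_table([
            ("chr1", 10, "g1", [(3, 5)] * 4),
            ("chr1", 20, "g1", [(7, 5)] * 4),
        ])
        m = aggregate(table, level="gene")
        assert m.counts.loc["g1"].tolist() == [10, 10] * 4

    def test_snp_level_is_reshape(self, make_count_table):
        table = make_count_table([
            ("chr1", 10, "g1", [(3, 5), (1, 1), (0, 2), (4, 4)]),
            ("chr1", 20, "g2", [(7, 5), (2, 2), (3, 0), (5, 5)]),
        ])
        m = aggregate(table, level="snp")
        assert list(m.counts.index) == ["chr1:10:g1", "chr1:20:g2"]
        assert m.counts.iloc[0].tolist() == [3, 5, 1, 1, 0, 2, 4, 4]

    def test_exonic_only_drops_intronic(self, make_count_table):
        table = make_count_table([
            ("chr1", 10, "g1", [(3, 5)] * 4),
            ("chr1", 15, "g1", [(100, 100)] * 4, "intronic"),
            ("chr1", 20, "g1", [(7, 5)] * 4),
        ])
        m = aggregate(table, level="gene", exonic_only=True)
        assert m.counts.loc["g1"].tolist() == [10, 10] * 4
        m_all = aggregate(table, level="gene", exonic_only=False)
        assert m_all.counts.loc["g1"].tolist() == [110, 110] * 4

    def test_exon_level_assignment(self, make_count_table):
        genes = [GeneModel("g1", "chr1", "+",
                           [GenomicInterval("chr1", 0, 50),
                            GenomicInterval("chr1", 100, 150)])]
        table = make_count_table([
            ("chr1", 10, "g1", [(3, 5)] * 4),
            ("chr1", 110, "g1", [(7, 5)] * 4),
            ("chr1", 120, "g1", [(2, 1)] * 4),
        ])
        m = aggregate(table, genes=genes, level="exon")
        assert sorted(m.counts.index) == ["g1:exon000", "g1:exon001"]
        assert m.counts.loc["g1:exon001"].tolist() == [9, 6] * 4


class TestFilterExclusive:
    def test_fully_b_exclusive_removed(self, make_count_table):
        table = make_count_table([
            ("chr1", 10, "g1", [(5, 0), (4, 0), (3, 0), (6, 0)]),
            ("chr1", 20, "g2", [(5, 1), (4, 2), (3, 1), (6, 2)]),
        ])
        kept, report = filter_exclusive(table)
        assert kept.df["gene_id"].tolist() == ["g2"]
        assert report["absent_allele"].tolist() == ["D"]

    def test_three_of_four_zero_is_retained(self, make_count_table):
        table = make_count_table([
            ("chr1", 10, "g1", [(5, 0), (4, 0), (3, 0), (6, 1)]),
        ])
        kept, report = filter_exclusive(table)
        assert kept.n_snps() == 1
        assert report.empty

    def test_error_snp_simulation_mostly_removed(self):
        _, _, truth, table = sim(seed=211, n_genes=400,
                                 fraction_error_snps=0.05)
        err_genes = {t.gene_id for t in truth if t.is_genotyping_error}
        err_rows = table.df["gene_id"].isin(err_genes)
        kept, _ = filter_exclusive(table)
        remaining = kept.df["gene_id"].isin(err_genes).sum()
        assert err_rows.sum() >= 10
        assert remaining <= 0.05 * err_rows.sum()


class TestSizeFactors:
    def test_identical_columns_are_unity(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_closed_form(self):
        c = np.array([10, 50, 200, 7])
        df = pd.DataFrame({"a": c, "b": 2 * c})
        sf = size_factors(df)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_global_bias_lands_in_b_factors(self):
        _, _, _, table = sim(seed=221, n_genes=500, global_bias=1.2,
                             fraction_cis=0.0, fraction_imprinted=0.0,
                             fraction_error_snps=0.0, nb_dispersion=0.0)
        m = aggregate(table, level="gene")
        sf = size_factors(m)
        b_cols = [c for c in m.counts.columns if c.endswith(".B")]
        d_cols = [c for c in m.counts.columns if c.endswith(".D")]
        ratio = sf[b_cols].mean() / sf[d_cols].mean()
        assert ratio == pytest.approx(1.2, rel=0.05)

    def test_no_allpositive_unit_needs_fallback(self):
        df = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(df)
        sf = size_factors(df, pseudo_reference=True)
        assert np.isfinite(sf).all()


class TestEstimateDispersion:
    def test_identical_replicates_have_zero_empirical(self):
        m = make_matrix([[100, 100, 50, 50]], labels_by_allele=True)
        f = pd.Series(1.0, index=m.counts.columns)
        dm = estimate_dispersion(m, ContrastDesign("strain"), f)
        assert dm.empirical.iloc[0] == 0.0
        assert dm.working.iloc[0] == dm.fitted.iloc[0]

    def test_moment_formula(self):
        # B condition (80, 120), D condition (80, 120), factors 1:
        # pooled var 800, mean 100 -> alpha = (800 - 100) / 100^2 = 0.07
        m = make_matrix([[80, 120, 80, 120]], labels_by_allele=True)
        f = pd.Series(1.0, index=m.counts.columns)
        dm = estimate_dispersion(m, ContrastDesign("strain"), f)
        assert dm.empirical.iloc[0] == pytest.approx(0.07)

    def test_single_replicate_rejected(self):
        cols = ["m1.B", "m1.D"]
        counts = pd.DataFrame([[5, 6]], columns=cols, index=["u1"])
        meta = pd.DataFrame({"sample": ["m1", "m1"], "allele": ["B", "D"],
                             "cross": ["BxD", "BxD"], "sex": ["F", "F"]},
                            index=cols)
        m = CountMatrix(counts, meta, "gene")
        f = pd.Series(1.0, index=cols)
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersion(m, ContrastDesign("strain"), f)

    def test_parameter_recovery_at_2000_units(self):
        rng = np.random.default_rng(2)
        n, alpha = 2000, 0.05
        mu = rng.lognormal(np.log(200), 0.5, n)
        counts = rng.negative_binomial(
            1 / alpha, 1 / (1 + alpha * mu[:, None]), size=(n, 8))
        m = make_matrix(counts, labels_by_allele=True)
        f = size_factors(m.counts)
        dm = estimate_dispersion(m, ContrastDesign("strain"), f)
        assert np.median(dm.working) == pytest.approx(alpha, rel=0.25)


class TestNBExactTest:
    def test_balanced_counts_give_p_one(self):
        p = nb_exact_test(np.array([50, 50, 50, 50]),
                          np.array(["B", "D", "B", "D"]),
                          np.ones(4), 0.05)
        assert p == 1.0

    def test_zero_total_gives_p_one(self):
        p = nb_exact_test(np.zeros(4), np.array(["B", "D", "B", "D"]),
                          np.ones(4), 0.05)
        assert p == 1.0

    def test_binomial_limit_on_grid(self):
        """As dispersion -> 0 with equal factors the conditional split is
        binomial; agreement within 10% relative on a 50-case grid."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(20, 500))
            a = int(rng.integers(0, n + 1))
            p_nb = nb_exact_test(np.array([a, n - a], dtype=float),
                                 np.array(["B", "D"]), np.ones(2), 1e-9)
            p_bin = stats.binomtest(a, n, 0.5).pvalue
            assert p_nb == pytest.approx(p_bin, rel=0.10)

    def test_null_pvalues_uniform(self):
        """Global-null NB counts with the true dispersion give uniform
        p-values (KS not rejecting at 1%)."""
        rng = np.random.default_rng(0)
        alpha, mu = 0.05, 250
        labels = np.array(["B"] * 4 + ["D"] * 4)
        f = np.ones(8)
        ps = np.array([
            nb_exact_test(
                rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), 8),
                labels, f, alpha)
            for _ in range(1000)
        ])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_normal_approximation_at_boundary(self):
        """The large-total normal approximation agrees with full enumeration
        near the switch point."""
        rng = np.random.default_rng(8)
        labels = np.array(["B", "D", "B", "D"])
        f = np.ones(4)
        for _ in range(10):
            k = rng.poisson(2600, size=4).astype(float)  # total ~10400
            exact = nb_exact_test(k, labels, f, 0.02, exact_limit=10 ** 9)
            approx = nb_exact_test(k, labels, f, 0.02, exact_limit=1)
            assert approx == pytest.approx(exact, rel=0.15, abs=1e-4)

    def test_missing_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.array([1, 2]), np.array(["B", "D"]),
                          np.ones(2), float("nan"))


class TestFisherSnp:
    def test_symmetric_table_is_one(self):
        assert fisher_snp_test(20, 20, 1000, 1000) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        b, d, bt, dt = 30, 10, 1000, 1000
        n = b + d
        pmf = np.array([stats.hypergeom.pmf(x, bt + dt, bt, n)
                        for x in range(n + 1)])
        p_expect = pmf[pmf <= pmf[b] * (1 + 1e-9)].sum()
        assert fisher_snp_test(b, d, bt, dt) == pytest.approx(p_expect,
                                                              rel=1e-6)

    def test_zero_margin_is_one(self):
        assert fisher_snp_test(0, 0, 0, 0) == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 40), st.integers(0, 40))
    def test_enumeration_oracle_on_small_tables(self, b, d, extra_b, extra_d):
        bt, dt = b + extra_b, d + extra_d
        p = fisher_snp_test(b, d, bt, dt)
        assert 0 < p <= 1
        n = b + d
        if n > 0 and bt + dt > n:
            pmf = np.array([stats.hypergeom.pmf(x, bt + dt, bt, n)
                            for x in range(n + 1)])
            expect = pmf[pmf <= pmf[b] * (1 + 1e-9)].sum()
            assert p == pytest.approx(min(expect, 1.0), rel=1e-6, abs=1e-12)


class TestBHFdr:
    def test_stepup_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, float("nan")])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_adjustment_bounds(self, pvals):
        padj = bh_fdr(pvals)
        assert (padj >= np.asarray(pvals) - 1e-12).all()
        assert (padj <= 1.0).all()


class TestRunContrast:
    def test_label_swap_negates_log2fc(self, make_count_table):
        rows = [("chr1", int(i * 100), f"g{i}",
                 [(int(b), int(d)) for b, d in
                  np.random.default_rng(i).integers(20, 200, size=(4, 2))])
                for i in range(30)]
        table = make_count_table(rows)
        res = run_contrast(aggregate(table, level="gene"),
                           ContrastDesign("strain"))
        # swap the two alleles in every sample
        swapped_rows = [(c, p, g, [(d, b) for b, d in cs])
                        for c, p, g, cs in rows]
        table_sw = make_count_table(swapped_rows)
        res_sw = run_contrast(aggregate(table_sw, level="gene"),
                              ContrastDesign("strain"))
        assert np.allclose(res_sw["log2fc"], -res["log2fc"])
        assert np.allclose(res_sw["pval"], res["pval"])

    def test_strong_effect_detected_with_direction(self):
        cfg, ann, truth, table = sim(seed=231, n_genes=200, fraction_cis=0.0,
                                     fraction_imprinted=0.0,
                                     fraction_error_snps=0.0,
                                     mean_coverage=2000)
        # inject one strong D-up gene
        truth[7].ase_log2fc = 3.0
        table = synth.gen_counts(ann, truth, cfg)
        res = run_contrast(aggregate(table, level="gene"),
                           ContrastDesign("strain"))
        gid = truth[7].gene_id
        assert res.loc[gid, "significant"]
        assert res.loc[gid, "direction"] == "D"

    def test_parent_mode_null_under_pure_cis(self):
        _, _, _, table = sim(seed=233, n_genes=500, fraction_cis=0.15,
                             fraction_imprinted=0.0, fraction_error_snps=0.0,
                             fraction_sex_specific=0.0)
        res = run_contrast(aggregate(table, level="gene"),
                           ContrastDesign("parent"))
        assert res["significant"].mean() <= 0.01

    def test_sex_filter_restricts_columns(self):
        _, _, _, table = sim(seed=235, n_genes=100)
        m = aggregate(table, level="gene")
        res_m = run_contrast(m, ContrastDesign("strain", sex_filter="male"))
        res_all = run_contrast(m, ContrastDesign("strain"))
        assert len(res_m) == len(res_all)
        assert not np.allclose(res_m["pval"], res_all["pval"])


class TestFisherPipeline:
    def test_intersection_rule(self, make_count_table):
        # background of balanced genes, one gene strong in only 3 samples,
        # one strong everywhere
        rows = [("chr1", int(i * 100), f"bg{i}", [(100, 100)] * 4)
                for i in range(20)]
        rows.append(("chr1", 5000, "g3of4",
                     [(300, 30), (300, 30), (300, 30), (100, 100)]))
        rows.append(("chr1", 6000, "gall",
                     [(300, 30), (300, 30), (300, 30), (300, 30)]))
        table = make_count_table(rows)
        out = fisher_pipeline(table, levels=("gene",))["gene"]
        assert not out.loc["g3of4", "called"]
        assert out.loc["gall", "called"]
        assert out.loc["gall", "direction"] == "B"

    def test_nb_at_least_as_sensitive_at_matched_fdr(self):
        _, _, truth, table = sim(seed=241, n_genes=800, mean_coverage=500)
        table, _ = filter_exclusive(table)
        tf = synth.truth_frame(truth).set_index("gene_id")
        cis = set(tf.index[(tf.ase_log2fc != 0) & ~tf.is_genotyping_error])
        res = run_contrast(aggregate(table, level="gene"),
                           ContrastDesign("strain"))
        nb_called = set(res.index[res["significant"]])
        tp_nb = len(nb_called & cis)
        fdr_nb = (len(nb_called) - tp_nb) / max(len(nb_called), 1)
        fish = fisher_pipeline(table, levels=("gene",))["gene"]
        tp_fisher = 0
        for a in (0.05, 0.01, 3e-3, 1e-3, 3e-4, 1e-4, 1e-5):
            calls = asetest.fisher_calls(fish, a)
            called = set(calls.index[calls["called"]])
            tp = len(called & cis)
            fdr = (len(called) - tp) / max(len(called), 1)
            if fdr <= fdr_nb + 1e-12:
                tp_fisher = tp
                break
        assert tp_nb >= tp_fisher


class TestReplicateTitration:
    def test_full_k_matches_run_contrast(self):
        _, _, _, table = sim(seed=251, n_genes=150)
        m = aggregate(table, level="gene")
        design = ContrastDesign("strain")
        tit = replicate_titration(m, design, [4])
        full = run_contrast(m, design)
        assert tit.loc[0, "n_significant"] == full["significant"].sum()
        assert tit.loc[0, "overlap_with_full"] == full["significant"].sum()

    def test_k_below_two_rejected(self):
        _, _, _, table = sim(seed=251, n_genes=50)
        m = aggregate(table, level="gene")
        with pytest.raises(ValueError):
            replicate_titration(m, ContrastDesign("strain"), [1])

    def test_power_increases_with_replicates(self):
        counts2, counts4 = [], []
        for seed in range(261, 266):
            _, _, _, table = sim(seed=seed, n_genes=300)
            m = aggregate(table, level="gene")
            tit = replicate_titration(m, ContrastDesign("strain"), [2, 4])
            counts2.append(tit.loc[0, "n_significant"])
            counts4.append(tit.loc[1, "n_significant"])
        assert np.mean(counts4) >= np.mean(counts2)


class TestCompareSexes:
    def test_identical_results_fully_concordant(self):
        _, _, _, table = sim(seed=271, n_genes=100)
        res = run_contrast(aggregate(table, level="gene"),
                           ContrastDesign("strain"))
        out = compare_sexes(res, res)
        assert out["r2"] == pytest.approx(1.0)
        assert out["n_both"] == out["n_either"]

    def test_independent_null_simulations_uncorrelated(self):
        _, _, _, t1 = sim(seed=273, n_genes=300, fraction_cis=0.0,
                          fraction_imprinted=0.0, fraction_error_snps=0.0)
        _, _, _, t2 = sim(seed=274, n_genes=300, fraction_cis=0.0,
                          fraction_imprinted=0.0, fraction_error_snps=0.0)
        r1 = run_contrast(aggregate(t1, level="gene"),
                          ContrastDesign("strain"))
        r2 = run_contrast(aggregate(t2, level="gene"),
                          ContrastDesign("strain"))
        out = compare_sexes(r1, r2)
        assert out["r2"] < 0.05

    def test_male_only_effects_enrich_male_calls(self):
        cfg, ann, truth, _ = sim(seed=275, n_genes=600, fraction_cis=0.10,
                                 fraction_sex_specific=1.0,
                                 fraction_imprinted=0.0,
                                 fraction_error_snps=0.0,
                                 mean_coverage=800)
        # force sex-specific cis genes to male_only
        for t in truth:
            if t.ase_log2fc != 0:
                t.sex_specificity = "male_only"
        table = synth.gen_counts(ann, truth, cfg)
        m = aggregate(table, level="gene")
        res_m = run_contrast(m, ContrastDesign("strain", sex_filter="male"))
        res_f = run_contrast(m, ContrastDesign("strain", sex_filter="female"))
        out = compare_sexes(res_m, res_f)
        male_only = {t.gene_id for t in truth
                     if t.sex_specificity == "male_only"}
        spec = set(out["male_specific"])
        overlap = len(spec & male_only)
        # male-specific calls should be heavily enriched for male_only truth
        tab = [[overlap, len(spec) - overlap],
               [len(male_only) - overlap,
                600 - len(spec) - len(male_only) + overlap]]
        assert stats.fisher_exact(tab, alternative="greater")[1] < 0.01


class TestModelAPI:
    def test_fit_returns_results_with_summary(self):
        _, _, _, table = sim(seed=281, n_genes=80)
        model = ASEModel.from_count_table(table, level="gene", mode="strain")
        res = model.fit()
        text = res.summary()
        assert "strain" in text and "units tested:        80" in text
        assert res.frame["padj"].between(0, 1).all()
        assert (res.frame["padj"] >= res.frame["pval"] - 1e-12).all()
        sig = res.frame["significant"]
        assert (sig == (res.frame["padj"] < res.alpha)).all()

    def test_plot_ma_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        _, _, _, table = sim(seed=281, n_genes=80)
        res = ASEModel.from_count_table(table).fit()
        ax = res.plot_ma()
        assert ax.get_xlabel() == "mean normalized count"
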