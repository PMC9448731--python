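"""Enrichment/DE statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tissuewalk import stats as tw
from tissuewalk import synthetic as syn


def hypergeom_upper_tail(k, n_universe, n_a, n_b):
    """Exact enumeration oracle: P(overlap >= k) by summing comb terms."""
    total = math.comb(n_universe, n_b)
    acc = 0
    for j in range(k, min(n_a, n_b) + 1):
        if n_universe - n_a >= n_b - j:
            acc += math.comb(n_a, j) * math.comb(n_universe - n_a, n_b - j)
    return acc / total


class TestFisherOverlap:
    def test_disjoint_sets_p_near_one(self):
        res = tw.fisher_overlap({"a", "b"}, {"c", "d"}, 1000)
        assert res.overlap == 0
        assert res.pvalue == pytest.approx(1.0)

    def test_identical_sets_minimal_tail(self):
        res = tw.fisher_overlap({"a", "b", "c"}, {"a", "b", "c"}, 6)
        assert res.pvalue == pytest.approx(1 / math.comb(6, 3))

    def test_printed_toy_table(self):
        """N=20, |A|=|B|=5, overlap 4: tail = (5*15 + 1)/C(20,5)."""
        a = {f"x{i}" for i in range(5)}
        b = set(list(a)[:4]) | {"y"}
        res = tw.fisher_overlap(a, b, 20)
        assert res.overlap == 4
        assert res.pvalue == pytest.approx(76 / 15504)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            tw.fisher_overlap({"a", "b"}, {"c"}, 2)

    def test_zero_margin_flags_continuity(self):
        res = tw.fisher_overlap({"a"}, {"a"}, 2)
        assert res.continuity

    def test_matches_enumeration_for_small_universes(self):
        """Spot grid of the exhaustive check run in full by the acceptance
        suite: agreement with comb-sum enumeration for N <= 30."""
        for n_universe in (5, 12, 23, 30):
            for n_a in range(0, n_universe + 1, 4):
                for n_b in range(0, n_universe + 1, 5):
                    k_min = max(0, n_a + n_b - n_universe)
                    for k in range(k_min, min(n_a, n_b) + 1):
                        universe = [f"g{i}" for i in range(n_universe)]
                        a = set(universe[:n_a])
                        b = set(universe[:k]) | set(universe[n_a:n_a + n_b - k])
                        res = tw.fisher_overlap(a, b, n_universe)
                        oracle = hypergeom_upper_tail(k, n_universe, n_a, n_b)
                        assert res.pvalue == pytest.approx(oracle, abs=1e-12)


class TestTwoProportionZ:
    def test_equal_proportions_z_zero(self):
        res = tw.two_proportion_ztest(16, 100, 16, 100)
        assert res.z == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_all_zero(self):
        res = tw.two_proportion_ztest(0, 10, 0, 10)
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_hand_pooled_formula(self):
        """(30,100) vs (10,100): z = 0.2/sqrt(0.2*0.8*0.02)."""
        res = tw.two_proportion_ztest(30, 100, 10, 100)
        z_hand = 0.2 / math.sqrt(0.2 * 0.8 * (1 / 100 + 1 / 100))
        assert res.z == pytest.approx(z_hand)
        assert res.pvalue == pytest.approx(2 * sps.norm.sf(z_hand))
        assert res.pvalue == pytest.approx(4.1e-4, rel=0.05)

    def test_antisymmetry(self):
        a = tw.two_proportion_ztest(30, 90, 12, 80)
        b = tw.two_proportion_ztest(12, 80, 30, 90)
        assert a.z == pytest.approx(-b.z)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest
        z_ref, p_ref = proportions_ztest([23, 11], [70, 65])
        res = tw.two_proportion_ztest(23, 70, 11, 65)
        assert res.z == pytest.approx(z_ref)
        assert res.pvalue == pytest.approx(p_ref)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            tw.two_proportion_ztest(5, 4, 1, 10)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert tw.bh_fdr([0.04]) == pytest.approx([0.04])

    def test_all_equal_ps_unchanged(self):
        assert tw.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_step_up_triple(self):
        """p=(0.01, 0.02, 0.9): step-up gives q=(0.03, 0.03, 0.9)."""
        assert tw.bh_fdr([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        perm = rng.permutation(25)
        assert tw.bh_fdr(p[perm]) == pytest.approx(tw.bh_fdr(p)[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tw.bh_fdr([0.1, 1.5])


class TestEnrichmentProportions:
    def test_single_domain_proportion_one(self):
        table = tw.enrichment_proportions(
            ["g1", "g2"], {"g1": "cytosol", "g2": "cytosol"})
        assert table.proportion.tolist() == [1.0]

    def test_hand_counted_toy(self):
        genes = [f"g{i}" for i in range(10)]
        annot = {g: "cytosol" for g in genes[:6]}
        annot.update({g: "nucleus" for g in genes[6:]})
        table = tw.enrichment_proportions(genes, annot)
        by_label = dict(zip(table.label, table.proportion))
        assert by_label == {"cytosol": pytest.approx(0.6),
                            "nucleus": pytest.approx(0.4)}

    def test_multi_label_genes_count_once_per_label(self):
        table = tw.enrichment_proportions(
            ["g1"], {"g1": ["cytosol", "nucleus"]})
        assert set(table["count"]) == {1}
        assert len(table) == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tw.enrichment_proportions([], {})


class TestMaxTissueAssignment:
    def test_single_expressed_column(self):
        expr = pd.DataFrame({"cortex": [5.0], "liver": [0.0]}, index=["g1"])
        assert tw.max_tissue_assignment(expr)["g1"] == "cortex"

    def test_tie_takes_first_column(self):
        expr = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["g1"])
        assert tw.max_tissue_assignment(expr)["g1"] == "a"

    def test_zero_rows_excluded(self):
        expr = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 0.5]},
                            index=["dead", "live"])
        out = tw.max_tissue_assignment(expr)
        assert "dead" not in out.index

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.random((5, 3)) + 0.1,
                            index=[f"g{i}" for i in range(5)],
                            columns=["t1", "t2", "t3"])
        out = tw.max_tissue_assignment(expr)
        for g in expr.index:
            assert out[g] == expr.columns[int(np.argmax(expr.loc[g].to_numpy()))]


class TestPrenatalPostnatalDe:
    @staticmethod
    def make_instance(de_effect, n_genes=300, seed=3):
        cfg = syn.SimulationConfig(
            n_genes=n_genes, module_size=0, seed_fraction=0.0, n_regions=1,
            n_stage_reps=3, de_fraction=0.5, de_effect=de_effect,
            noise_sd=1.0, rng_seed=seed,
        )
        uni = syn.generate_universe(cfg)
        expr, meta = syn.generate_dev_expression(uni, cfg)
        return cfg, uni, expr, meta

    def test_large_effect_detected_with_power_one(self):
        cfg = syn.SimulationConfig(
            n_genes=60, module_size=0, seed_fraction=0.0, n_regions=1,
            n_stage_reps=20, de_fraction=0.3, de_effect=10.0, noise_sd=1.0,
            rng_seed=6,
        )
        uni = syn.generate_universe(cfg)
        expr, meta = syn.generate_dev_expression(uni, cfg)
        table = tw.prenatal_postnatal_de(expr, meta, "region_01")
        # planted genes are exactly those whose pre/post means differ
        pre = meta.loc[meta.stage_bin.isin(syn.PRENATAL_BINS), "sample_id"]
        post = meta.loc[meta.stage_bin.isin(syn.POSTNATAL_BINS), "sample_id"]
        shift = (expr[list(post)].mean(axis=1)
                 - expr[list(pre)].mean(axis=1)).abs() > 5
        planted = set(shift[shift].index)
        called = set(table.loc[table.de, "gene"])
        assert planted <= called

    def test_null_calibration_raw_p(self):
        _, _, expr, meta = self.make_instance(de_effect=0.0, n_genes=1000)
        table = tw.prenatal_postnatal_de(expr, meta, "region_01")
        frac = (table.pvalue < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert table.de.sum() <= 5

    def test_single_gene_bh_identity(self):
        # one gene: q equals p, DE iff p < alpha
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "region": ["r"] * 8,
            "stage_bin": ["0-12_pcw"] * 4 + ["0-2_yr"] * 4,
        })
        expr = pd.DataFrame([np.r_[rng.normal(0, 1, 4), rng.normal(4, 1, 4)]],
                            index=["g1"], columns=meta.sample_id)
        table = tw.prenatal_postnatal_de(expr, meta, "r")
        assert table.qvalue.iloc[0] == pytest.approx(table.pvalue.iloc[0])

    def test_insufficient_samples_names_region(self):
        meta = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "region": ["r"] * 3,
            "stage_bin": ["0-12_pcw", "0-2_yr", "0-2_yr"],
        })
        expr = pd.DataFrame(np.zeros((2, 3)), index=["g1", "g2"],
                            columns=meta.sample_id)
        with pytest.raises(ValueError, match="'r'"):
            tw.prenatal_postnatal_de(expr, meta, "r")

    def test_region_summary_counts_de_regions(self):
        tables = {
            "r1": pd.DataFrame({"gene": ["g1", "g2"], "de": [True, False]}),
            "r2": pd.DataFrame({"gene": ["g1", "g2"], "de": [True, True]}),
        }
        out = tw.de_region_summary(tables, ["g1", "g2", "g3"])
        by_gene = dict(zip(out.gene, out.n_de_regions))
        assert by_gene == {"g1": 2, "g2": 1, "g3": 0}


class TestCellTypeIntersection:
    def test_empty_lists_give_empty_intersections(self):
        out = tw.intersect_with_celltype_de(["g1"], {"Exc": [], "In": []})
        assert (out.n_intersection == 0).all()

    def test_full_overlap_returns_candidates(self):
        out = tw.intersect_with_celltype_de(["g1", "g2"], {"Exc": ["g1", "g2"]})
        assert out.n_intersection.iloc[0] == 2

    def test_matches_set_oracle(self):
        novel = ["g1", "g2", "g3"]
        lists = {"Exc": ["g2", "g9"], "Ast": ["g3", "g1"]}
        out = tw.intersect_with_celltype_de(
            novel, lists, cell_class={"Exc": "neuronal", "Ast": "glial"})
        by_ct = {r.cell_type: set(r.genes.split(";")) if r.genes else set()
                 for r in out.itertuples()}
        for ct, de in lists.items():
            assert by_ct[ct] == set(novel) & set(de)


class TestPercent:
    def test_rounding_matches_report_style(self):
        assert tw.percent(154, 247) == 62.0
        assert tw.percent(22, 57) == 39.0
        assert tw.percent(38, 3205, ndigits=1) == 1.2

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tw.percent(1, 0)
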