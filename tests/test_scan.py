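"""Scan orchestration: thresholds, FDR, variance fractions, regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pedgwas as pg
from pedgwas.mixed_model import VarianceComponents
from pedgwas.scan import merge_regions


class TestBonferroni:
    def test_basic_and_rounded(self):
        assert pg.bonferroni_threshold(0.05, 1) == 0.05
        thr = pg.bonferroni_threshold(0.05, 408_255)
        assert thr == pytest.approx(1.2247e-7, rel=1e-4)
        assert pg.bonferroni_threshold(0.05, 408_255, magnitude_rounding=True) == 1e-7

    def test_rounding_no_op_on_power_of_ten(self):
        assert pg.bonferroni_threshold(0.05, 500_000) == pytest.approx(1e-7)
        assert pg.bonferroni_threshold(
            0.05, 500_000, magnitude_rounding=True
        ) == pytest.approx(1e-7)


class TestFdrPercent:
    @pytest.mark.parametrize(
        "p,S,T,expected",
        [
            (0.0001, 136, 408_255, 30),
            (0.01, 5, 136, 26),
            (0.01, 1, 40, 39),
            (0.01, 3, 36, 11),
            (0.0001, 5, 9_180, 18),
        ],
    )
    def test_stage_fdrs(self, p, S, T, expected):
        assert round(pg.fdr_percent(p, S, T)) == expected

    def test_hit_rate_equal_to_threshold_gives_100(self):
        assert pg.fdr_percent(0.01, 10, 1000) == pytest.approx(100.0)

    def test_can_exceed_100(self):
        assert pg.fdr_percent(0.05, 1, 100) > 100.0

    def test_zero_hits_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pg.fdr_percent(0.01, 0, 100))

    @given(
        p1=st.floats(1e-6, 0.2),
        p2=st.floats(1e-6, 0.2),
        S=st.integers(1, 50),
        T=st.integers(51, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_p_and_s(self, p1, p2, S, T):
        lo, hi = sorted([p1, p2])
        if lo < hi:
            assert pg.fdr_percent(lo, S, T) < pg.fdr_percent(hi, S, T)
        assert pg.fdr_percent(lo, S, T) > pg.fdr_percent(lo, S + 1, T)


class TestVarianceFraction:
    def test_additive_at_half_frequency(self):
        vc = VarianceComponents(30.0, 20.0, 50.0)
        sigma2, frac = pg.variance_fraction(1.0, 0.5, vc, "additive")
        assert sigma2 == pytest.approx(0.5)
        assert frac == pytest.approx(0.5)

    def test_dominance_at_half_frequency(self):
        vc = VarianceComponents(30.0, 20.0, 50.0)
        sigma2, _ = pg.variance_fraction(1.0, 0.5, vc, "dominance")
        assert sigma2 == pytest.approx(0.25)

    def test_allele_relabel_symmetry(self):
        vc = VarianceComponents(0.3, 0.1, 0.6)
        for kind in ("additive", "dominance"):
            s1, f1 = pg.variance_fraction(0.8, 0.3, vc, kind)
            s2, f2 = pg.variance_fraction(-0.8, 0.7, vc, kind)
            assert s1 == pytest.approx(s2)
            assert f1 == pytest.approx(f2)


def sig_table(positions, chrom="1", pvals=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "pos": positions,
            "p": pvals or np.linspace(1e-8, 1e-6, n),
            "estimate": np.ones(n),
            "flags": [""] * n,
        }
    )


class TestMergeRegions:
    def test_gap_splits_regions(self):
        regions = merge_regions(
            sig_table([1_000_000, 1_400_000, 5_000_000]), gap_bp=1_000_000
        )
        assert len(regions) == 2
        assert regions.iloc[0]["start_bp"] == 1_000_000
        assert regions.iloc[0]["end_bp"] == 1_400_000
        assert regions.iloc[1]["start_bp"] == regions.iloc[1]["end_bp"]

    def test_single_snp_degenerate_region(self):
        regions = merge_regions(sig_table([123]), gap_bp=1_000_000)
        assert len(regions) == 1
        assert regions.iloc[0]["start_bp"] == regions.iloc[0]["end_bp"] == 123

    def test_all_within_gap_single_region_and_counts(self):
        tab = sig_table([1, 500_000, 900_000, 1_200_000])
        regions = merge_regions(tab, gap_bp=1_000_000)
        assert len(regions) == 1
        assert regions.iloc[0]["n_snps"] == len(tab)

    def test_top_snp_smallest_p_tie_smaller_bp(self):
        tab = sig_table([100, 200], pvals=[1e-8, 1e-8])
        regions = merge_regions(tab, gap_bp=1_000)
        assert regions.iloc[0]["top_snp"] == "s0"

    def test_member_counts_sum_to_significant(self):
        rng = np.random.default_rng(0)
        tab = sig_table(sorted(rng.integers(1, 10**7, 30).tolist()))
        regions = merge_regions(tab, gap_bp=300_000)
        assert regions["n_snps"].sum() == len(tab)


class TestRunScan:
    def test_planted_additive_qtl_found(self, small_scan_inputs):
        ds, resp, A, vc, stats = small_scan_inputs
        res = pg.run_scan(ds.panel, stats, resp, vc, A, "additive")
        causal = ds.truth.causal_effects[0]["snp"]
        top = res.table.sort_values("p").iloc[0]
        if top["snp"] != causal:
            # accept a tag in strong LD with the causal marker
            g1 = ds.panel.snp_codes(causal).astype(float)
            g2 = ds.panel.snp_codes(top["snp"]).astype(float)
            assert np.corrcoef(g1, g2)[0, 1] ** 2 > 0.8
        assert res.table.loc[res.table["snp"] == causal, "p"].iloc[0] < 1e-2

    def test_scan_output_invariant_to_snp_input_order(self, small_scan_inputs):
        ds, resp, A, vc, stats = small_scan_inputs
        res1 = pg.run_scan(ds.panel, stats, resp, vc, A, "additive")
        perm = np.random.default_rng(1).permutation(ds.panel.n_snps)
        shuffled = ds.panel.subset_snps(perm)
        res2 = pg.run_scan(shuffled, stats, resp, vc, A, "additive")
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_dominance_scan_reports_d_effect(self, small_scan_inputs):
        ds, resp, A, vc, stats = small_scan_inputs
        res = pg.run_scan(ds.panel, stats, resp, vc, A, "dominance")
        assert (res.table.loc[res.table["flags"] == "", "effect_name"] == "d_j").all()

    def test_overdominant_qtl_missed_by_additive_found_by_dominance(self):
        """A pure-dominance locus (a=0, d>0) is invisible to the additive
        contrast but significant in the dominance scan."""
        cfg = pg.SimulationConfig(
            seed=77, n_founders=120, n_generations=2,
            n_offspring_per_generation=700, n_cows=600, n_snps=40,
            n_chromosomes=1, records_min=1, records_max=2,
            sigma_g2=0.05, sigma_pe2=0.05, sigma_e2=0.9,
            causal_additive=((5, 0.0, 0.8),),
        )
        ds = pg.simulate_dataset(cfg)
        model = pg.fit_fixed_effects(ds.phenotypes)
        resp = pg.residualize(
            ds.phenotypes, model, genotyped_ids=ds.panel.animal_ids
        )
        A = pg.build_A(pg.prune_to_ancestors(ds.pedigree, ds.panel.animal_ids))
        vc = pg.reml_null(resp, A)
        stats = pg.allele_stats(ds.panel)
        causal = ds.truth.causal_effects[0]["snp"]
        add = pg.run_scan(ds.panel, stats, resp, vc, A, "additive")
        dom = pg.run_scan(ds.panel, stats, resp, vc, A, "dominance")
        p_add = add.table.set_index("snp").loc[causal, "p"]
        p_dom = dom.table.set_index("snp").loc[causal, "p"]
        assert p_dom < 1e-4
        assert p_add > 1e-3

    def test_null_scan_calibration(self):
        """With no causal loci, S/T at threshold 0.05 stays near 0.05."""
        cfg = pg.SimulationConfig(
            seed=55, n_founders=80, n_generations=2,
            n_offspring_per_generation=320, n_cows=300, n_snps=400,
            n_chromosomes=4, records_min=1, records_max=2,
        )
        ds = pg.simulate_dataset(cfg)
        model = pg.fit_fixed_effects(ds.phenotypes)
        resp = pg.residualize(
            ds.phenotypes, model, genotyped_ids=ds.panel.animal_ids
        )
        A = pg.build_A(pg.prune_to_ancestors(ds.pedigree, ds.panel.animal_ids))
        vc = pg.reml_null(resp, A)
        stats = pg.allele_stats(ds.panel)
        res = pg.run_scan(
            ds.panel, stats, resp, vc, A, "additive", threshold=0.05
        )
        rate = res.n_significant / res.n_tests
        # markers are in LD so the binomial SE underestimates; allow 3x with
        # an LD cushion
        se = np.sqrt(0.05 * 0.95 / res.n_tests)
        assert abs(rate - 0.05) < 5 * se

    def test_manhattan_tsv(self, small_scan_inputs, tmp_path):
        ds, resp, A, vc, stats = small_scan_inputs
        res = pg.run_scan(ds.panel, stats, resp, vc, A, "additive")
        out = tmp_path / "manhattan.tsv"
        pg.write_manhattan(res, out)
        back = pd.read_csv(out, sep="\t")
        assert list(back.columns) == ["chrom", "pos", "snp", "neglog10p", "variant"]
        assert len(back) == ds.panel.n_snps
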