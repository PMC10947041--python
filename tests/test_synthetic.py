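import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbsvkit.caller import call_mbsvs, consensus_filter
from mbsvkit.io import MHC_HG19
from mbsvkit.synthetic import (
    SimulationConfig,
    TruthLabels,
    simulate_all,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas,
    simulate_site_scores,
)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_mbsv=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(ld_rho=1.0)

    def test_enrichment_requires_mbsvs(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_mbsv=0.0, frac_enriched=0.5)

    def test_nonfinite_shift_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(enrichment_shift=float("inf"))


class TestSimulateGwas:
    def test_empty_config_gives_empty_tables(self):
        gwas, truth = simulate_gwas(SimulationConfig(
            n_variants=0, n_mhc=0, n_nonautosomal=0, frac_mbsv=0.0))
        assert len(gwas) == 0 and len(truth.variants) == 0

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(n_variants=500, seed=42)
        a, ta = simulate_gwas(cfg)
        b, tb = simulate_gwas(cfg)
        assert a.to_csv() == b.to_csv()
        assert ta.variants.to_csv() == tb.variants.to_csv()

    def test_null_pvalues_are_uniform(self):
        cfg = SimulationConfig(n_variants=10_000, enrichment_shift=0.0, seed=5,
                               n_mhc=0, n_nonautosomal=0)
        gwas, _ = simulate_gwas(cfg)
        d, p_ks = stats.kstest(gwas["p"], "uniform")
        # K-S distance below the alpha = 0.01 critical value for n = 10^4
        critical = stats.kstwobign.isf(0.01) / np.sqrt(len(gwas))
        assert d < critical
        for t in (0.05, 1e-3):
            frac = (gwas["p"] < t).mean()
            se = np.sqrt(t * (1 - t) / len(gwas))
            assert abs(frac - t) <= 3 * se

    def test_enriched_variants_shifted(self):
        cfg = SimulationConfig(n_variants=4_000, frac_mbsv=0.25, frac_enriched=0.8,
                               enrichment_shift=2.0, seed=6)
        gwas, truth = simulate_gwas(cfg)
        enr = truth.variants["is_enriched"]
        assert enr.sum() == round(0.8 * truth.variants["is_mbsv"].sum())
        assert (truth.variants["is_enriched"] <= truth.variants["is_mbsv"]).all()
        p = gwas.set_index("variant_id")["p"]
        assert p[enr[enr].index].median() < p[enr[~enr].index].median()

    def test_truth_delta_nonzero_iff_mbsv(self):
        _, truth = simulate_gwas(SimulationConfig(n_variants=1_000, seed=7))
        tv = truth.variants
        assert ((tv["true_delta"] != 0) == tv["is_mbsv"]).all()

    def test_effect_and_p_mutually_consistent(self):
        gwas, _ = simulate_gwas(SimulationConfig(n_variants=2_000, seed=8))
        alt_eff = np.where(gwas["effect_allele"] == gwas["alt"],
                           gwas["log_effect"], -gwas["log_effect"])
        z = alt_eff / gwas["se"]
        assert np.allclose(2 * stats.norm.sf(np.abs(z)), gwas["p"])
        assert (gwas["effect_allele"] == gwas["ref"]).any()

    def test_mhc_and_x_subsets_placed(self):
        gwas, _ = simulate_gwas(SimulationConfig(n_variants=2_000, seed=9,
                                                 n_mhc=15, n_nonautosomal=5))
        in_mhc = gwas.apply(lambda r: MHC_HG19.contains(r["chrom"], r["pos"]), axis=1)
        assert in_mhc.sum() == 15
        assert (gwas["chrom"] == "X").sum() == 5


class TestSimulateGenotypes:
    def test_independent_variants_have_null_level_r2(self):
        cfg = SimulationConfig(n_variants=200, n_samples_panel=300, ld_rho=0.0,
                               seed=10, n_mhc=0, n_nonautosomal=0)
        gwas, _ = simulate_gwas(cfg)
        panel = simulate_genotypes(cfg, gwas)
        sub = panel.iloc[:, :60].to_numpy(dtype=float)
        r2 = np.corrcoef(sub, rowvar=False) ** 2
        off = r2[np.triu_indices_from(r2, k=1)]
        # E[r^2] = 1/(n-1) under independence
        assert np.mean(off) == pytest.approx(1 / (300 - 1), rel=0.3)

    def test_near_duplicate_latents_give_high_r2(self):
        cfg = SimulationConfig(n_variants=440, n_samples_panel=400, ld_rho=0.999,
                               maf_range=(0.3, 0.3), seed=11,
                               ld_block_size=20, n_mhc=0, n_nonautosomal=0)
        gwas, _ = simulate_gwas(cfg)
        # one chromosome = one 20-variant block sharing a latent factor
        gwas = gwas[gwas["chrom"] == "1"]
        assert len(gwas) == 20
        panel = simulate_genotypes(cfg, gwas)
        g = panel.to_numpy(dtype=float)
        r2 = np.corrcoef(g, rowvar=False) ** 2
        assert np.median(r2[np.triu_indices_from(r2, k=1)]) > 0.9

    def test_dosages_and_determinism(self):
        cfg = SimulationConfig(n_variants=100, n_samples_panel=50, seed=12)
        gwas, _ = simulate_gwas(cfg)
        a = simulate_genotypes(cfg, gwas)
        b = simulate_genotypes(cfg, gwas)
        assert a.equals(b)
        assert a.isin([0, 1, 2]).all(axis=None)

    def test_small_panel_rejected(self):
        cfg = SimulationConfig(n_samples_panel=1)
        with pytest.raises(ValueError, match="2 samples"):
            simulate_genotypes(cfg, pd.DataFrame(columns=["chrom", "maf", "variant_id"]))


class TestSimulateSiteScores:
    def build(self, **kw):
        cfg = SimulationConfig(n_variants=300, seed=13, frac_mbsv=0.1,
                               frac_decoy=0.3, **kw)
        gwas, truth = simulate_gwas(cfg)
        *_, (exp_g, exp_m) = simulate_expression(cfg)
        truth.expressed_genes, truth.expressed_mirnas = exp_g, exp_m
        sites = simulate_site_scores(cfg, gwas, truth)
        return cfg, gwas, truth, sites

    def test_caller_recovers_true_deltas_exactly(self):
        _, _, truth, sites = self.build()
        called = call_mbsvs(consensus_filter(sites), truth.expressed_genes,
                            truth.expressed_mirnas)
        got = called.set_index("variant_id")["delta"]
        want = truth.variants.loc[truth.variants["is_mbsv"], "true_delta"]
        assert set(got.index) == set(want.index)
        assert np.allclose(got.sort_index(), want.sort_index())

    def test_no_mbsvs_means_no_calls(self):
        cfg = SimulationConfig(n_variants=200, seed=14, frac_mbsv=0.0,
                               frac_decoy=0.3)
        gwas, truth = simulate_gwas(cfg)
        *_, (exp_g, exp_m) = simulate_expression(cfg)
        truth.expressed_genes, truth.expressed_mirnas = exp_g, exp_m
        sites = simulate_site_scores(cfg, gwas, truth)
        called = call_mbsvs(consensus_filter(sites), exp_g, exp_m)
        assert len(called) == 0

    def test_each_decoy_class_violates_its_filter(self):
        _, _, truth, sites = self.build()
        tv = truth.variants
        called = set(call_mbsvs(consensus_filter(sites), truth.expressed_genes,
                                truth.expressed_mirnas)["variant_id"])
        decoys = tv[tv["decoy_class"] != ""]
        assert len(decoys) > 0
        assert set(decoys.index).isdisjoint(called)
        # classes that rely on location must sit on the right variants
        for vid in decoys.index[decoys["decoy_class"] == "nonautosomal"]:
            assert vid.startswith("X:")

    def test_missing_truth_variant_rejected(self):
        cfg, gwas, truth, _ = self.build()
        extra = truth.variants.copy()
        extra.loc["9:1:A:G"] = [True, False, 0.5, ""]
        bad = TruthLabels(extra, truth.expressed_genes, truth.expressed_mirnas)
        with pytest.raises(ValueError, match="absent"):
            simulate_site_scores(cfg, gwas, bad)


class TestSimulateExpression:
    def test_known_pass_fail_split(self):
        cfg = SimulationConfig(seed=15)
        gene_rpkm, mirna_counts, libs, tiers, fam, sets, (exp_g, exp_m) = \
            simulate_expression(cfg)
        frac = (gene_rpkm >= 1.0).mean(axis=1)
        assert set(gene_rpkm.index[frac >= 0.75]) == exp_g
        cpm = mirna_counts / (libs / 1e6)
        thr = 10 / (libs.min() / 1e6)
        passing = (cpm >= thr).mean(axis=1) >= 0.75
        confident = pd.Series(tiers).ne(
            "poorly conserved and possibly misannotated as a miRNA")
        assert set(mirna_counts.index[passing & confident]) == exp_m

    def test_family_map_total_and_determinism(self):
        cfg = SimulationConfig(seed=16)
        out1 = simulate_expression(cfg)
        out2 = simulate_expression(cfg)
        fam = out1[4]
        assert fam.index.size == cfg.n_mirnas and not fam.isna().any()
        assert out1[0].equals(out2[0]) and out1[1].equals(out2[1])


def test_simulate_all_is_internally_consistent(dataset):
    d = dataset
    assert set(d.panel.columns) == set(d.gwas["variant_id"])
    assert d.truth.variants.index.equals(pd.Index(d.gwas["variant_id"],
                                                  name="variant_id"))
    assert (d.truth.variants["is_enriched"] <= d.truth.variants["is_mbsv"]).all()
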