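"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svomics.omics import rank_normalize
from svomics.qtl import fit_qtl
from svomics.simulate import (
    SimulationConfig,
    ld_feasibility_bound,
    plant_rare_outliers,
    simulate_genotypes,
    simulate_gwas_summary,
    simulate_methylation,
    simulate_phenotypes,
    write_fixture_dir,
)
from svomics.variants import MISSING, genotype_r2


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = SimulationConfig(n_samples=120, n_svs=30, n_snvs=40, seed=5,
                               n_genes=20, n_proteins=20)
        a_svs, a_snvs = simulate_genotypes(cfg)
        b_svs, b_snvs = simulate_genotypes(cfg)
        assert np.array_equal(a_svs.genotypes, b_svs.genotypes)
        assert np.array_equal(a_snvs.genotypes, b_snvs.genotypes)
        ea, pa, ca, _ = simulate_phenotypes(a_svs, cfg)
        eb, pb, cb, _ = simulate_phenotypes(b_svs, cfg)
        assert ea.values.equals(eb.values)
        assert np.allclose(pa.values, pb.values)
        assert ca.equals(cb)

    def test_gwas_table_deterministic(self):
        R = np.eye(8)
        t1, _ = simulate_gwas_summary(R, {2: 5.0}, n=1000, seed=9)
        t2, _ = simulate_gwas_summary(R, {2: 5.0}, n=1000, seed=9)
        assert t1.equals(t2)


class TestLdTargets:
    def test_perfect_ld_duplicates_columns(self):
        cfg = SimulationConfig(n_samples=200, n_svs=5, n_snvs=5, seed=1,
                               ld_targets=[("sv_1", "snv_1", 1.0)],
                               missing_rate=0.0)
        svs, snvs = simulate_genotypes(cfg)
        assert np.array_equal(svs.column("sv_1"), snvs.column("snv_1"))

    def test_zero_ld_target_independent(self):
        cfg = SimulationConfig(n_samples=2000, n_svs=5, n_snvs=5, seed=2,
                               ld_targets=[("sv_1", "snv_1", 0.0)],
                               maf_overrides={"sv_1": 0.3},
                               missing_rate=0.0)
        svs, snvs = simulate_genotypes(cfg)
        r2 = genotype_r2(svs.column("sv_1"), snvs.column("snv_1"))
        assert r2 < 0.01

    def test_intermediate_target_within_tolerance(self):
        cfg = SimulationConfig(n_samples=800, n_svs=5, n_snvs=5, seed=3,
                               ld_targets=[("sv_1", "snv_1", 0.6)],
                               maf_overrides={"sv_1": 0.25},
                               missing_rate=0.0)
        svs, snvs = simulate_genotypes(cfg)
        r2 = genotype_r2(svs.column("sv_1"), snvs.column("snv_1"))
        assert abs(r2 - 0.6) <= 0.1

    def test_infeasible_target_rejected(self):
        # MAF 0.01 vs 0.5: r2 bound = 0.01*0.5/(0.99*0.5) ~ 0.0101
        assert ld_feasibility_bound(0.01, 0.5) == pytest.approx(
            0.01 * 0.5 / (0.99 * 0.5))
        cfg = SimulationConfig(
            n_samples=500, n_svs=5, n_snvs=5, seed=4,
            ld_targets=[("sv_1", "snv_1", 0.9)],
            maf_overrides={"sv_1": 0.01, "snv_1": 0.5})
        with pytest.raises(ValueError, match="feasibility"):
            simulate_genotypes(cfg)


class TestMafSpectrum:
    def test_point_mass_maf_realized(self):
        n, p = 500, 40
        cfg = SimulationConfig(n_samples=n, n_svs=p, n_snvs=0, seed=6,
                               maf_beta=(1e6, 1e6), maf_min=0.2499,
                               missing_rate=0.0)
        # beta(1e6,1e6) concentrates at 0.5 of the [maf_min, 0.5] range
        svs, _ = simulate_genotypes(cfg)
        af = svs.genotypes.mean(axis=0) / 2
        target = 0.2499 + 0.5 * (0.5 - 0.2499)
        se = np.sqrt(target * (1 - target) / (2 * n * p))
        assert abs(af.mean() - target) < 3 * se

    def test_missing_rate_injected(self):
        cfg = SimulationConfig(n_samples=400, n_svs=50, n_snvs=0, seed=7,
                               missing_rate=0.05)
        svs, _ = simulate_genotypes(cfg)
        frac = (svs.genotypes == MISSING).mean()
        assert 0.03 < frac < 0.07

    def test_sv_records_carry_type_length_interval(self):
        cfg = SimulationConfig(n_samples=50, n_svs=200, n_snvs=0, seed=8)
        svs, _ = simulate_genotypes(cfg)
        for rec in svs.records:
            assert rec.vtype in ("INS", "DEL", "DUP", "INV")
            assert rec.length >= 50
        lengths = np.array([r.length for r in svs.records])
        # mobile-element mode near 300 bp dominates
        assert ((lengths > 200) & (lengths < 450)).mean() > 0.25


class TestPhenotypes:
    def test_null_correlations_match_theory(self):
        cfg = SimulationConfig(n_samples=300, n_svs=20, n_snvs=0, seed=9,
                               n_genes=10, n_proteins=200,
                               n_hidden_factors=0, covariate_effects={},
                               missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, prot, _, _ = simulate_phenotypes(svs, cfg)
        g = svs.genotypes[:, 0].astype(float)
        P = prot.values.to_numpy()
        rs = np.array([np.corrcoef(g, P[:, j])[0, 1] for j in range(200)])
        # null |r| 95th percentile ~ 1.96/sqrt(n)
        q95 = np.quantile(np.abs(rs), 0.95)
        assert q95 == pytest.approx(1.96 / np.sqrt(300), rel=0.35)

    def test_planted_beta_recovered_by_ols(self):
        cfg = SimulationConfig(n_samples=600, n_svs=10, n_snvs=0, seed=10,
                               qtl_effects=[("sv_2", "prot_4", 0.5)],
                               maf_overrides={"sv_2": 0.3},
                               n_genes=5, n_proteins=10,
                               n_hidden_factors=0, covariate_effects={},
                               missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, prot, _, _ = simulate_phenotypes(svs, cfg)
        g = svs.column("sv_2").astype(float)
        gs = (g - g.mean()) / g.std()
        beta, se, _ = fit_qtl(prot.values["prot_4"].to_numpy(), gs)
        assert abs(beta - 0.5) < 2 * se

    def test_zero_noise_single_effect_collinear(self):
        cfg = SimulationConfig(n_samples=100, n_svs=5, n_snvs=0, seed=11,
                               qtl_effects=[("sv_1", "prot_1", 1.0)],
                               maf_overrides={"sv_1": 0.4},
                               n_genes=5, n_proteins=5,
                               n_hidden_factors=0, covariate_effects={},
                               noise_sd=0.0, missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, prot, _, _ = simulate_phenotypes(svs, cfg)
        g = svs.column("sv_1").astype(float)
        r = np.corrcoef(g, prot.values["prot_1"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_feature_reference_rejected(self):
        cfg = SimulationConfig(n_samples=50, n_svs=5, n_snvs=0, seed=12,
                               qtl_effects=[("sv_1", "nope_1", 0.5)],
                               n_genes=5, n_proteins=5)
        svs, _ = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_phenotypes(svs, cfg)

    def test_ground_truth_records_each_effect_once(self):
        effects = [("sv_1", "prot_1", 0.5), ("sv_2", "gene_2", 0.3)]
        cfg = SimulationConfig(n_samples=200, n_svs=5, n_snvs=0, seed=13,
                               qtl_effects=effects,
                               maf_overrides={"sv_1": 0.3, "sv_2": 0.3},
                               n_genes=5, n_proteins=5, missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, _, _, truth = simulate_phenotypes(svs, cfg)
        recorded = [(e["variant_id"], e["feature"], e["beta"])
                    for e in truth.qtl_effects]
        assert sorted(recorded) == sorted(effects)


class TestRareOutlierPlanting:
    def test_or_one_plants_nothing(self):
        cfg = SimulationConfig(n_samples=300, n_svs=30, n_snvs=0, seed=14,
                               n_genes=5, n_proteins=50,
                               n_hidden_factors=0, covariate_effects={},
                               missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, prot, _, _ = simulate_phenotypes(svs, cfg)
        mat, truth = plant_rare_outliers(svs, prot, target_or=1.0, seed=1)
        assert truth.rare_outlier_pairs == []
        assert np.allclose(mat.values, prot.values)

    def test_unreachable_or_without_carriers_rejected(self):
        cfg = SimulationConfig(n_samples=100, n_svs=10, n_snvs=0, seed=15,
                               n_genes=5, n_proteins=10, missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, prot, _, _ = simulate_phenotypes(svs, cfg)
        with pytest.raises(ValueError, match="unreachable"):
            # no SV qualifies at an absurd rarity threshold
            plant_rare_outliers(svs, prot, target_or=5.0, af_rare=1e-9,
                                seed=1)

    def test_explicit_negative_shift_creates_under_outlier(self):
        cfg = SimulationConfig(n_samples=400, n_svs=10, n_snvs=0, seed=16,
                               n_genes=5, n_proteins=20,
                               maf_overrides={"sv_3": 0.01},
                               n_hidden_factors=0, covariate_effects={},
                               missing_rate=0.0)
        svs, _ = simulate_genotypes(cfg)
        _, prot, _, _ = simulate_phenotypes(svs, cfg)
        mat, truth = plant_rare_outliers(
            svs, prot, pairs=[("sv_3", "prot_7", -6.0)], seed=1)
        assert truth.rare_outlier_pairs
        X = mat.values.to_numpy()
        z = (X - X.mean(0)) / X.std(0)
        col = list(mat.values.columns).index("prot_7")
        carriers = [list(mat.values.index).index(p["sample"])
                    for p in truth.rare_outlier_pairs]
        assert all(z[c, col] < -2 for c in carriers)


class TestMethylationGenerator:
    def test_zero_cpg_noise_gives_perfect_within_segment_correlation(self):
        cfg = SimulationConfig(n_samples=80, n_segments=10, seed=17,
                               cpg_noise_sd=0.0, segment_latent_sd=0.05,
                               frac_variable_segments=0.0)
        betas, positions, truth = simulate_methylation(cfg)
        B = betas.to_numpy()
        for members in truth.segments:
            if len(members) < 2:
                continue
            a, b = members[0], members[1]
            if B[:, a].std() == 0:
                continue
            assert np.corrcoef(B[:, a], B[:, b])[0, 1] == pytest.approx(
                1.0, abs=1e-12)

    def test_cross_segment_latents_independent(self):
        cfg = SimulationConfig(n_samples=500, n_segments=40, seed=18,
                               cpg_noise_sd=0.0, segment_latent_sd=0.1,
                               frac_variable_segments=0.0)
        betas, _, truth = simulate_methylation(cfg)
        B = betas.to_numpy()
        firsts = [m[0] for m in truth.segments]
        rs = []
        for i in range(0, 30, 2):
            a, b = firsts[i], firsts[i + 1]
            if B[:, a].std() > 0 and B[:, b].std() > 0:
                rs.append(abs(np.corrcoef(B[:, a], B[:, b])[0, 1]))
        assert np.mean(rs) < 0.1

    def test_clip_count_reported(self):
        cfg = SimulationConfig(n_samples=100, n_segments=30, seed=19,
                               methylation_outliers=[(0, 0, 5.0)])
        _, _, truth = simulate_methylation(cfg)
        assert truth.clip_count > 0


class TestGwasGenerator:
    def test_null_pvalues_uniform(self):
        R = np.eye(400)
        table, _ = simulate_gwas_summary(R, {}, n=10_000, seed=20)
        stat, p = stats.kstest(table["p"], "uniform")
        assert p > 0.01

    def test_causal_variant_attains_smallest_p(self):
        R = np.eye(25)
        wins = 0
        for seed in range(100):
            table, _ = simulate_gwas_summary(R, {11: 8.0}, n=1000, seed=seed)
            wins += table["p"].idxmin() == 11
        assert wins >= 99

    def test_non_psd_matrix_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_gwas_summary(R, {}, n=100, seed=0)

    def test_ld_spreads_signal(self):
        k = 10
        R = 0.9 ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        table, _ = simulate_gwas_summary(R, {4: 8.0}, n=1000, seed=3)
        z = table["z"].to_numpy()
        assert abs(z[3]) > 2  # neighbor inherits signal through LD


class TestFixtureDir:
    def test_write_and_reread_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_samples=40, n_svs=15, n_snvs=20, seed=21,
                               n_genes=10, n_proteins=10, n_segments=10)
        paths = write_fixture_dir(str(tmp_path), cfg)
        from svomics.variants import read_variant_vcf
        svs = read_variant_vcf(paths["sv_vcf"])
        assert svs.n_variants == 15
        expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        assert expr.shape == (40, 10)
        cov = pd.read_csv(paths["covariates"], sep="\t", index_col=0)
        assert set(cov.columns) == {"age", "sex", "dx"}
        assert (tmp_path / "ground_truth.json").exists()
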