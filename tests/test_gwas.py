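"""GRM formulas, REML variance components, and the MLMA scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from awmnet.datatypes import Grm, TraitTable, ValidationError
from awmnet.gwas import (
    GrmEigen,
    compute_grm,
    mlma_scan,
    reml_null,
    run_all_gwas,
    zscore_effects,
)
from awmnet.simulate import SimConfig, simulate_dataset
from conftest import make_genotypes


class TestGrm:
    def test_off_diagonal_single_snp(self):
        # dosages 2 and 0 at p = 0.5: (2-1)(0-1)/(2*0.5*0.5) = -2
        g = make_genotypes([[2.0], [0.0]])
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.values[0, 1], -2.0)

    def test_diagonal_single_heterozygote(self):
        # dosage 1 at p = 0.5: 1 + (1 - 2 + 0.5)/0.5 = 0 for that sample
        g = make_genotypes([[1.0], [2.0], [0.0]])  # p = 0.5
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.values[0, 0], 0.0, atol=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.5, 5000)
        dos = rng.binomial(2, p, size=(200, 5000)).astype(float)
        grm = compute_grm(make_genotypes(dos))
        assert 0.97 < np.diag(grm.values).mean() < 1.03

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.3, size=(30, 100)).astype(float)
        g = make_genotypes(dos)
        grm = compute_grm(g)
        perm = rng.permutation(30)
        grm_p = compute_grm(make_genotypes(dos[perm]))
        np.testing.assert_allclose(grm_p.values, grm.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_monomorphic_snp_guard(self):
        g = make_genotypes([[2.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="monomorphic"):
            compute_grm(g)

    def test_missing_dosages_mean_imputed(self):
        dos = np.array([[2.0, 1.0], [0.0, np.nan], [1.0, 0.0], [1.0, 1.0]])
        grm = compute_grm(make_genotypes(dos))
        assert np.all(np.isfinite(grm.values))


def _simulate_grm_pheno(n, m, h2, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    g = make_genotypes(dos)
    grm = compute_grm(g)
    w = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
    beta = rng.standard_normal(m) * np.sqrt(h2 / m)
    gv = w @ beta
    y = gv + rng.standard_normal(n) * np.sqrt(max(1 - h2, 1e-12))
    return y, g, grm


class TestReml:
    def test_recovers_moderate_heritability(self):
        ests = []
        for seed in range(20):
            y, _, grm = _simulate_grm_pheno(500, 2000, 0.5, 1000 + seed)
            ests.append(reml_null(y, grm, compute_se=False).h2)
        assert 0.45 < np.mean(ests) < 0.55

    def test_null_phenotype_gives_near_zero(self):
        # sampling SD of h2-hat is ~ sqrt(2m)/n, so n >> sqrt(m) keeps
        # the null estimate pinned near the zero boundary
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, _, grm = _simulate_grm_pheno(800, 400, 0.5, 2000 + seed)
            y = rng.standard_normal(800)
            if reml_null(y, grm, compute_se=False).h2 <= 0.05:
                hits += 1
        assert hits >= 18

    def test_identity_grm_flags_flat_likelihood(self):
        rng = np.random.default_rng(3)
        grm = Grm(np.eye(100), 1, [f"s{i}" for i in range(100)])
        est = reml_null(rng.standard_normal(100), grm)
        assert est.flat_likelihood and not est.converged

    def test_lambda_within_broad_factor_of_truth(self):
        ratios = []
        for seed in range(20):
            y, _, grm = _simulate_grm_pheno(500, 2000, 0.5, 3000 + seed)
            est = reml_null(y, grm, compute_se=False)
            if est.sigma_e2 > 0 and est.sigma_u2 > 0:
                ratios.append(est.sigma_u2 / est.sigma_e2)
        assert 0.7 < np.mean(ratios) < 1.4  # truth: lambda = 1

    def test_constant_phenotype_rejected(self):
        _, _, grm = _simulate_grm_pheno(50, 100, 0.5, 5)
        with pytest.raises(ValidationError, match="constant"):
            reml_null(np.ones(50), grm)

    def test_standard_errors_finite(self):
        y, _, grm = _simulate_grm_pheno(300, 1000, 0.5, 99)
        est = reml_null(y, grm, compute_se=True)
        assert np.isfinite(est.se_h2) and 0 < est.se_h2 < 1


class TestMlma:
    def test_zero_polygenic_variance_equals_ols(self):
        from awmnet.datatypes import VarianceEstimate

        y = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([[0.0], [1.0], [1.0], [2.0]])
        g = make_genotypes(s)
        grm = Grm(np.eye(4), 1, g.sample_ids)
        vc = VarianceEstimate(0.0, 1.0, 0.0, 0, 0, 0, 0.0, True)
        res = mlma_scan(y, g, grm, vc)
        np.testing.assert_allclose(res.table["effect"].iloc[0], 1.5, atol=1e-10)

    def test_matches_linear_regression_without_grm(self):
        from awmnet.datatypes import VarianceEstimate

        rng = np.random.default_rng(12)
        dos = rng.binomial(2, 0.3, size=(80, 20)).astype(float)
        y = rng.standard_normal(80)
        g = make_genotypes(dos)
        grm = Grm(np.eye(80), 20, g.sample_ids)
        vc = VarianceEstimate(0.0, 1.0, 0.0, 0, 0, 0, 0.0, True)
        res = mlma_scan(y, g, grm, vc)
        for j in range(20):
            slope = stats.linregress(dos[:, j], y).slope
            np.testing.assert_allclose(res.table["effect"].iloc[j], slope, atol=1e-8)

    def test_duplicate_snp_identical_statistics(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        dos[:, 2] = dos[:, 0]
        g = make_genotypes(dos)
        grm = compute_grm(make_genotypes(rng.binomial(2, 0.3, (100, 200)).astype(float)))
        grm = Grm(grm.values, grm.m_snps, g.sample_ids)
        y = rng.standard_normal(100)
        vc = reml_null(y, grm, compute_se=False)
        res = mlma_scan(y, g, grm, vc)
        for col in ("effect", "se", "z", "p"):
            np.testing.assert_allclose(
                res.table[col].iloc[0], res.table[col].iloc[2], atol=1e-12
            )

    def test_zero_variance_snp_reported_missing(self):
        from awmnet.datatypes import VarianceEstimate

        dos = np.column_stack([np.ones(10) * 1.0, np.arange(10) % 3.0])
        g = make_genotypes(dos)
        grm = Grm(np.eye(10), 2, g.sample_ids)
        vc = VarianceEstimate(0.0, 1.0, 0.0, 0, 0, 0, 0.0, True)
        res = mlma_scan(np.random.default_rng(0).standard_normal(10), g, grm, vc)
        assert np.isnan(res.table["effect"].iloc[0])
        assert res.table["reason"].iloc[0] == "zero_variance"
        assert res.table["reason"].iloc[1] == ""

    def test_p_consistent_with_wald(self):
        y, g, grm = _simulate_grm_pheno(150, 300, 0.4, 55)
        vc = reml_null(y, grm, compute_se=False)
        res = mlma_scan(y, g, grm, vc)
        expect = 2 * stats.norm.sf(np.abs(res.table["z"]))
        np.testing.assert_allclose(res.table["p"], expect, atol=1e-10)


class TestRunAllGwas:
    def test_result_complete_and_duplicate_trait_identical(self):
        cfg = SimConfig(n_breeds=1, n_per_breed=120, n_snps=300, n_genes=30,
                        n_traits=4, n_causal_genes=6, seed=19)
        data = simulate_dataset(cfg)
        b = cfg.breed_names[0]
        t = data.traits[b]
        # append a copy of trait 2
        values = np.column_stack([t.values, t.values[:, 1]])
        traits = TraitTable(t.sample_ids, t.trait_names + ["copy"], values)
        res, vcs = run_all_gwas(traits, data.genotypes[b])
        assert len(res.table) == 5 * 300
        a = res.table[res.table["trait"] == t.trait_names[1]]["p"].to_numpy()
        c = res.table[res.table["trait"] == "copy"]["p"].to_numpy()
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_causal_snp_ranks_high_for_key_trait(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_breeds=1, n_per_breed=400, n_snps=500, n_genes=50,
                            n_traits=4, n_causal_genes=3, h2=0.6,
                            causal_var_fraction=0.95, seed=600 + seed)
            data = simulate_dataset(cfg)
            b = cfg.breed_names[0]
            res, _ = run_all_gwas(data.traits[b], data.genotypes[b])
            key = res.table[res.table["trait"] == "KEY"].set_index("snp")
            cutoff = np.quantile(key["p"], 0.01)
            causal = [s for s in data.truth.causal_snp_ids[b] if s in key.index]
            if any(key.loc[s, "p"] <= cutoff for s in causal):
                hits += 1
        assert hits >= 18

    def test_loco_scan_complete_and_close_to_default(self):
        cfg = SimConfig(n_breeds=1, n_per_breed=200, n_snps=400, n_genes=40,
                        n_traits=3, n_causal_genes=5, n_chromosomes=4,
                        h2=0.4, seed=61)
        data = simulate_dataset(cfg)
        b = cfg.breed_names[0]
        res, _ = run_all_gwas(data.traits[b], data.genotypes[b], loco=True)
        assert len(res.table) == 3 * 400
        # LOCO and non-LOCO agree closely on a polygenic-light panel
        default, _ = run_all_gwas(data.traits[b], data.genotypes[b])
        t = res.table[res.table["trait"] == "KEY"].set_index("snp")["effect"]
        d = default.table[default.table["trait"] == "KEY"].set_index("snp")["effect"]
        r = np.corrcoef(t.loc[d.index], d)[0, 1]
        assert r > 0.98

    def test_sparse_trait_skipped(self):
        cfg = SimConfig(n_breeds=1, n_per_breed=80, n_snps=200, n_genes=20,
                        n_traits=3, n_causal_genes=4, seed=29)
        data = simulate_dataset(cfg)
        b = cfg.breed_names[0]
        t = data.traits[b]
        values = t.values.copy()
        values[40:, 2] = np.nan  # 40 records < the 50-record minimum
        traits = TraitTable(t.sample_ids, t.trait_names, values)
        with pytest.warns(UserWarning, match="skipped"):
            res, _ = run_all_gwas(traits, data.genotypes[b])
        assert t.trait_names[2] not in res.traits


class TestZscore:
    def test_hand_arithmetic(self):
        table = pd.DataFrame(
            {
                "trait": ["t"] * 3,
                "snp": ["a", "b", "c"],
                "effect": [1.0, 2.0, 3.0],
                "se": 1.0, "z": 0.0, "p": 0.5, "n": 10,
            }
        )
        from awmnet.datatypes import GwasResult

        z = zscore_effects(GwasResult(table))
        np.testing.assert_allclose(z["t"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_normalization_contract(self):
        rng = np.random.default_rng(31)
        from awmnet.datatypes import GwasResult

        table = pd.DataFrame(
            {
                "trait": np.repeat(["t1", "t2"], 50),
                "snp": list(np.tile([f"s{i}" for i in range(50)], 2)),
                "effect": rng.standard_normal(100),
                "se": 1.0, "z": 0.0, "p": 0.5, "n": 10,
            }
        )
        z = zscore_effects(GwasResult(table))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_rejected(self):
        from awmnet.datatypes import GwasResult

        table = pd.DataFrame(
            {
                "trait": ["t"] * 3,
                "snp": ["a", "b", "c"],
                "effect": [2.0, 2.0, 2.0],
                "se": 1.0, "z": 0.0, "p": 0.5, "n": 10,
            }
        )
        with pytest.raises(ValidationError, match="t"):
            zscore_effects(GwasResult(table))
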