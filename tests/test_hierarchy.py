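"""Clustering, single-factor fits, factor GWAS and tree construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from treegwas import synthdata as sd
from treegwas.config import PipelineConfig
from treegwas.gencorr import build_corr_matrix
from treegwas.hierarchy import (HierarchyError, build_hierarchy, cluster_items,
                                derived_drink_traits, drop_misfit_items,
                                factor_gwas, fit_single_factor,
                                merge_correlated_factors,
                                propagate_sampling_corr)
from treegwas.io import tree_to_json


def block_corr(names, blocks, within, between):
    k = len(names)
    mat = np.full((k, k), between, float)
    for block in blocks:
        for a, b in itertools.product(block, repeat=2):
            mat[names.index(a), names.index(b)] = within
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=names, columns=names)


class TestClusterItems:
    def test_two_perfect_blocks_recovered(self):
        names = list("abcdef")
        corr = block_corr(names, [list("abc"), list("def")], 0.8, 0.0)
        groups, _ = cluster_items(corr)
        got = {frozenset(g) for g in groups}
        assert got == {frozenset("abc"), frozenset("def")}

    def test_agrees_with_brute_force_best_bipartition(self):
        """The 2-group cut maximizes within-group correlation among all
        bipartitions (enumerated exhaustively)."""
        names = list("abcdef")
        corr = block_corr(names, [list("abc"), list("def")], 0.8, 0.1)
        groups, _ = cluster_items(corr, n_groups=2)
        best, best_score = None, -np.inf
        for mask in range(1, 2 ** len(names) - 1):
            g1 = frozenset(n for i, n in enumerate(names) if mask >> i & 1)
            g2 = frozenset(names) - g1
            score = sum(corr.loc[a, b] for g in (g1, g2)
                        for a in g for b in g if a < b)
            if score > best_score:
                best, best_score = {g1, g2}, score
        assert {frozenset(g) for g in groups} == best

    def test_identity_yields_singletons(self):
        names = list("abcde")
        corr = pd.DataFrame(np.eye(5), index=names, columns=names)
        groups, _ = cluster_items(corr)
        assert all(len(g) == 1 for g in groups)
        groups_h, _ = cluster_items(corr, cut_height=1.0)
        assert all(len(g) == 1 for g in groups_h)

    def test_permutation_invariance(self, rng):
        names = list("abcdef")
        corr = block_corr(names, [list("abd"), list("cef")], 0.7, 0.1)
        groups, _ = cluster_items(corr)
        perm = list(rng.permutation(names))
        groups_p, _ = cluster_items(corr.loc[perm, perm])
        assert {frozenset(g) for g in groups} == {frozenset(g) for g in groups_p}

    def test_nan_correlations_rejected(self):
        corr = block_corr(list("abc"), [list("ab")], 0.5, 0.1)
        corr.iloc[0, 2] = np.nan
        corr.iloc[2, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cluster_items(corr)


class TestFitSingleFactor:
    def test_equicorrelated_triplet_closed_form(self):
        corr = block_corr(list("abc"), [list("abc")], 0.64, 0.0)
        fit = fit_single_factor(corr, n_eff=10_000)
        np.testing.assert_allclose(fit.loadings, 0.8, atol=1e-8)
        assert fit.srmr == pytest.approx(0.0, abs=1e-10)
        assert fit.cfi == pytest.approx(1.0, abs=1e-10)
        assert fit.fit_ok

    def test_identity_is_degenerate(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        fit = fit_single_factor(corr, n_eff=10_000)
        np.testing.assert_allclose(fit.loadings, 0.0, atol=1e-8)
        assert fit.srmr == pytest.approx(0.0, abs=1e-10)
        assert "degenerate" in fit.flags

    def test_recovers_heterogeneous_loadings_exactly(self):
        lam = np.array([0.9, 0.7, 0.5, 0.3])
        implied = np.outer(lam, lam)
        np.fill_diagonal(implied, 1.0)
        fit = fit_single_factor(implied, n_eff=10_000)
        np.testing.assert_allclose(fit.loadings, lam, atol=1e-6)
        assert fit.loadings.iloc[np.argmax(np.abs(fit.loadings))] > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_implied_matrices_fit_perfectly(self, seed):
        r = np.random.default_rng(seed)
        p = int(r.integers(3, 8))
        lam = r.uniform(0.2, 0.95, p)
        implied = np.outer(lam, lam)
        np.fill_diagonal(implied, 1.0)
        fit = fit_single_factor(implied, n_eff=50_000)
        assert fit.cfi == pytest.approx(1.0, abs=1e-10)
        assert fit.srmr == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(np.abs(fit.loadings), lam, atol=1e-6)

    def test_two_trait_convention(self):
        corr = pd.DataFrame([[1.0, 0.49], [0.49, 1.0]],
                            index=list("ab"), columns=list("ab"))
        fit = fit_single_factor(corr, n_eff=10_000)
        np.testing.assert_allclose(fit.loadings, 0.7, atol=1e-12)
        assert "underidentified_pair" in fit.flags


class TestDropMisfitItems:
    def misfit_group(self):
        names = list("abcd")
        mat = block_corr(names, [list("abc")], 0.64, 0.0)
        # d violates the one-factor structure: high with a, zero with b, c
        mat.loc["a", "d"] = mat.loc["d", "a"] = 0.7
        return mat

    def test_offending_item_removed(self):
        corr = self.misfit_group()
        kept, fit, removed, audit = drop_misfit_items(list("abcd"), corr,
                                                      n_eff=50_000)
        assert removed == ["d"]
        assert kept == list("abc")
        assert fit.fit_ok

    def test_objective_never_increases(self):
        corr = self.misfit_group()
        *_, audit = drop_misfit_items(list("abcd"), corr, n_eff=50_000)
        disc = [a["discrepancy"] for a in audit if "discrepancy" in a]
        assert all(x >= y - 1e-12 for x, y in zip(disc, disc[1:]))

    def test_passing_group_is_untouched(self):
        corr = block_corr(list("abc"), [list("abc")], 0.64, 0.0)
        kept, fit, removed, _ = drop_misfit_items(list("abc"), corr,
                                                  n_eff=50_000)
        assert kept == list("abc") and removed == []

    def test_uncorrelated_group_dissolves(self):
        corr = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        kept, fit, removed, _ = drop_misfit_items(list("abcd"), corr,
                                                  n_eff=50_000)
        assert kept is None
        assert set(removed) == set("abcd")


class TestFactorGwas:
    def sampling(self, names, rho=0.3):
        k = len(names)
        mat = np.full((k, k), rho)
        np.fill_diagonal(mat, 1.0)
        return pd.DataFrame(mat, index=names, columns=names)

    def test_symmetric_children_pass_through(self, make_stats):
        kids = [make_stats([0.07], 0.01, trait=t) for t in ("x", "y")]
        fs = factor_gwas(kids, {"x": 1.0, "y": 1.0}, self.sampling(["x", "y"]))
        assert fs.table["beta"].iloc[0] == pytest.approx(0.07, abs=1e-12)

    def test_hand_evaluated_combination(self, make_stats):
        kids = [make_stats([0.08], 0.01, trait=t) for t in ("x", "y")]
        fs = factor_gwas(kids, {"x": 0.8, "y": 0.8}, self.sampling(["x", "y"]))
        assert fs.table["beta"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_zero_loadings_rejected(self, make_stats):
        kids = [make_stats([0.05], 0.01, trait=t) for t in ("x", "y")]
        with pytest.raises(ValueError, match="loadings"):
            factor_gwas(kids, {"x": 0.0, "y": 0.0}, self.sampling(["x", "y"]))

    def test_matches_weighted_design_oracle(self, rng, make_stats):
        """Point estimate and sandwich SE equal an independently coded
        normal-equations evaluation of the loading-design combination."""
        for _ in range(20):
            k = int(rng.integers(2, 6))
            names = [f"t{i}" for i in range(k)]
            lam = rng.uniform(0.3, 0.95, k)
            betas = rng.normal(0, 0.05, k)
            ses = rng.uniform(0.005, 0.02, k)
            rho = self.sampling(names, rho=float(rng.uniform(0, 0.6)))
            kids = [make_stats([betas[i]], ses[i], trait=names[i])
                    for i in range(k)]
            fs = factor_gwas(kids, dict(zip(names, lam)), rho)
            denom = lam @ lam
            oracle_beta = lam @ betas / denom
            v = rho.to_numpy() * np.outer(ses, ses)
            oracle_se = np.sqrt(lam @ v @ lam) / denom
            assert fs.table["beta"].iloc[0] == pytest.approx(oracle_beta,
                                                             abs=1e-8)
            assert fs.table["se"].iloc[0] == pytest.approx(oracle_se, abs=1e-8)

    def test_factor_effect_recovery_coverage(self, make_stats):
        """SNP planted on the latent factor: the combined estimate covers
        the true effect within 2 SEs at the nominal rate."""
        hits = 0
        lam, true = 0.8, 0.05
        n = 20_000
        rho = self.sampling(["x", "y"], rho=0.64)
        for seed in range(100):
            r = np.random.default_rng(seed)
            chol = np.linalg.cholesky(rho.to_numpy())
            draw = lam * true + chol @ r.standard_normal(2) / np.sqrt(n)
            kids = [make_stats([draw[i]], 1 / np.sqrt(n), trait=t, n=n)
                    for i, t in enumerate(["x", "y"])]
            fs = factor_gwas(kids, {"x": lam, "y": lam}, rho)
            b, s = fs.table["beta"].iloc[0], fs.table["se"].iloc[0]
            hits += abs(b - true) <= 2 * s
        assert hits >= 93


class TestMergeFactors:
    def rg(self, vals):
        names = list(vals.columns) if isinstance(vals, pd.DataFrame) else None
        return vals

    def test_high_rg_pair_merges(self):
        rg = pd.DataFrame([[1, 0.95], [0.95, 1]], index=["f1", "f2"],
                          columns=["f1", "f2"])
        comps = merge_correlated_factors(rg, threshold=0.9)
        assert {frozenset(c) for c in comps} == {frozenset({"f1", "f2"})}

    def test_transitive_closure(self):
        rg = pd.DataFrame(np.eye(3), index=["f1", "f2", "f3"],
                          columns=["f1", "f2", "f3"])
        rg.loc["f1", "f2"] = rg.loc["f2", "f1"] = 0.95
        rg.loc["f2", "f3"] = rg.loc["f3", "f2"] = 0.95
        rg.loc["f1", "f3"] = rg.loc["f3", "f1"] = 0.5
        comps = merge_correlated_factors(rg, threshold=0.9)
        assert {frozenset(c) for c in comps} == {frozenset({"f1", "f2", "f3"})}

    def test_below_threshold_unchanged(self):
        rg = pd.DataFrame([[1, 0.85], [0.85, 1]], index=["f1", "f2"],
                          columns=["f1", "f2"])
        comps = merge_correlated_factors(rg, threshold=0.9)
        assert all(len(c) == 1 for c in comps)


def _independent_stats(seed, n_traits=5, m=2_000, n=50_000):
    spec = [{"id": f"t{i}"} for i in range(n_traits)]
    rng = np.random.default_rng(seed)
    causal = sd.polygenic_effects(rng, {f"t{i}": 0.1 for i in range(n_traits)},
                                  n_per_node=60, n_snps=m)
    cfg = sd.SimConfig(n_individuals=n, n_snps=m, tree_spec=spec,
                       causal_snps=causal, likert_levels=0, seed=seed)
    return sd.simulate_sumstats(cfg)


class TestBuildHierarchy:
    def test_independent_traits_give_empty_tree(self):
        stats, truth = _independent_stats(31)
        corr = build_corr_matrix(stats, rho_s=truth.pheno_corr, n_blocks=100)
        result = build_hierarchy(corr, stats, PipelineConfig(),
                                 sampling_corr=truth.pheno_corr)
        assert result.tree.factors() == []
        assert result.report["removed_items"] == []

    def test_rerun_is_deterministic(self):
        from treegwas.experiments import six_leaf_config
        cfg = six_leaf_config(17, m_snps=2_000, n_ind=20_000)
        stats, truth = sd.simulate_sumstats(cfg)
        corr = build_corr_matrix(stats, rho_s=truth.pheno_corr, n_blocks=100)
        r1 = build_hierarchy(corr, stats, PipelineConfig(),
                             sampling_corr=truth.pheno_corr)
        r2 = build_hierarchy(corr, stats, PipelineConfig(),
                             sampling_corr=truth.pheno_corr)
        assert tree_to_json(r1.tree) == tree_to_json(r2.tree)

    def test_too_few_traits_rejected(self, make_stats):
        from treegwas.gencorr import GeneticCorrMatrix
        names = ["a", "b", "c"]
        eye = pd.DataFrame(np.eye(3), index=names, columns=names)
        corr = GeneticCorrMatrix(traits=names, rg=eye, rg_se=eye * 0,
                                 h2=pd.Series(0.1, index=names),
                                 h2_se=pd.Series(0.01, index=names),
                                 rho_s=eye)
        stats = {t: make_stats([0.01], 0.01, trait=t) for t in names}
        with pytest.raises(ValueError, match="at least 4"):
            build_hierarchy(corr, stats, PipelineConfig())

    def test_sampling_corr_propagation_algebra(self):
        r = pd.DataFrame(np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3],
                                   [0.2, 0.3, 1.0]]),
                         index=list("abc"), columns=list("abc"))
        defs = {"f": (["a", "b"], [0.8, 0.6]), "c": (["c"], [1.0])}
        out = propagate_sampling_corr(r, defs)
        num = 0.8 * 0.2 + 0.6 * 0.3
        den = np.sqrt(0.64 + 0.36 + 2 * 0.8 * 0.6 * 0.5)
        assert out.loc["f", "c"] == pytest.approx(num / den, abs=1e-12)
        assert out.loc["f", "f"] == 1.0


def test_derived_drink_traits():
    pheno = pd.DataFrame({"sweet": [1.0, 5.0, 3.0], "plain": [4.0, 2.0, 3.0]})
    out = derived_drink_traits(pheno, "sweet", "plain", prefix="coffee")
    assert out["coffee_max"].tolist() == [4.0, 5.0, 3.0]
    assert out["coffee_diff"].tolist() == [-3.0, 3.0, 0.0]
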