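"""Reproducible simulation studies exercising the pipeline end to end.

Each function sets up a fully specified synthetic study (sample sizes,
SNP counts, planted effects), runs the relevant pipeline stages and returns
the measured quantities.  The test suite asserts on these numbers and the
acceptance script reports them, so the study conditions live in exactly one
place.  Problem sizes are chosen to finish in seconds to a few minutes on
one CPU; docs/methods.md records them.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from . import synthdata
from .config import PipelineConfig
from .effectflow import condition_subtree, decompose_all, SubTree
from .gencorr import build_corr_matrix, estimate_h2, estimate_rg
from .hierarchy import FactorTree, Node, build_hierarchy, _collect_factor_stats
from .locusmap import define_loci
from .pipeline import node_sampling_corr
from .sumstats import TraitSumStats

__all__ = [
    "two_trait_config",
    "six_leaf_config",
    "six_leaf_truth_tree",
    "rg_h2_recovery",
    "tree_recovery",
    "classification_study",
    "locus_oracle_check",
    "brute_force_loci",
    "conditional_oracle_check",
    "oracle_condition_subtree",
]


# ---------------------------------------------------------------------------
# reference study configurations
# ---------------------------------------------------------------------------

def two_trait_config(seed: int, m_snps: int = 5_000, n_ind: int = 10_000,
                     h2: float = 0.08, rg: float = 0.6) -> synthdata.SimConfig:
    """Two leaves under one factor with planted h2 and rg.

    With equal loadings lambda the shared genetic variance is rg * h2 and
    the leaf-specific variance is (1 - rg) * h2; loadings 0.8 put the shared
    part on the factor.
    """
    lam = 0.8
    shared = rg * h2 / lam ** 2
    specific = (1 - rg) * h2
    rng = np.random.default_rng(seed)
    causal = synthdata.polygenic_effects(
        rng, {"F": shared, "A": specific, "B": specific},
        n_per_node=200, n_snps=m_snps)
    tree = {"id": "F", "children": [
        {"id": "A", "loading": lam}, {"id": "B", "loading": lam}]}
    return synthdata.SimConfig(n_individuals=n_ind, n_snps=m_snps,
                               tree_spec=tree, causal_snps=causal,
                               likert_levels=0, seed=seed)


def six_leaf_config(seed: int, m_snps: int = 5_000, n_ind: int = 20_000,
                    extra_causal: list[tuple[int, str, float]] | None = None,
                    polygenic: bool = True) -> synthdata.SimConfig:
    """Two 3-leaf factors under one super-factor; leaf h2 = 0.10.

    Loadings: leaves 0.8 on their factor, factors 0.7 on the root.  The
    per-node genetic variances (root 0.1188, factor 0.0418, leaf 0.036) are
    chosen so that the genetic-correlation structure implies the generating
    loadings at every level *including* the top: leaf-specific genetic
    variance unavoidably leaks into the factor-level composite statistics
    (a leaf SNP with effect b contributes lambda b / sum(lambda^2) to the
    loading-weighted factor estimate), so the root share is sized such that
    the factor-level genetic correlation is exactly 0.49 = 0.7^2 after that
    leakage.  Leaf-level within/cross-factor rg are 0.64 and 0.373.
    """
    tree = {"id": "R", "children": [
        {"id": "F1", "loading": 0.7, "children": [
            {"id": "a1", "loading": 0.8}, {"id": "a2", "loading": 0.8},
            {"id": "a3", "loading": 0.8}]},
        {"id": "F2", "loading": 0.7, "children": [
            {"id": "b1", "loading": 0.8}, {"id": "b2", "loading": 0.8},
            {"id": "b3", "loading": 0.8}]}]}
    causal: list[tuple[int, str, float]] = []
    if polygenic:
        rng = np.random.default_rng(seed)
        causal = synthdata.polygenic_effects(
            rng,
            {"R": 0.1188, "F1": 0.0418, "F2": 0.0418,
             "a1": 0.036, "a2": 0.036, "a3": 0.036,
             "b1": 0.036, "b2": 0.036, "b3": 0.036},
            n_per_node=100, n_snps=m_snps)
    if extra_causal:
        used = {i for i, _, _ in causal}
        for idx, node, b in extra_causal:
            if idx in used:
                raise ValueError(f"extra causal SNP {idx} collides")
            causal.append((idx, node, b))
    return synthdata.SimConfig(n_individuals=n_ind, n_snps=m_snps,
                               tree_spec=tree, causal_snps=causal,
                               likert_levels=0, seed=seed)


def six_leaf_truth_tree() -> FactorTree:
    """The generating topology of :func:`six_leaf_config` as a FactorTree."""
    tree = FactorTree()
    for leaf in ("a1", "a2", "a3", "b1", "b2", "b3"):
        tree.nodes[leaf] = Node(id=leaf, label=leaf, level=0)
    tree.nodes["F1"] = Node(id="F1", label="F-F1", level=1,
                            children=["a1", "a2", "a3"],
                            loadings={k: 0.8 for k in ("a1", "a2", "a3")})
    tree.nodes["F2"] = Node(id="F2", label="F-F2", level=1,
                            children=["b1", "b2", "b3"],
                            loadings={k: 0.8 for k in ("b1", "b2", "b3")})
    tree.nodes["R"] = Node(id="R", label="F-R", level=2,
                           children=["F1", "F2"],
                           loadings={"F1": 0.7, "F2": 0.7})
    tree.roots = ["R"]
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def rg_h2_recovery(seed: int, n_reps: int = 200, m_snps: int = 5_000,
                   n_ind: int = 10_000, h2: float = 0.08,
                   rg: float = 0.6) -> dict[str, Any]:
    """Recover planted h2 and rg from summary-level simulations.

    Returns mean estimates, biases and the fraction of replicates whose
    estimate falls within 2 jackknife SEs of the truth.
    """
    h2_est, h2_cover, rg_est, rg_cover = [], [], [], []
    for rep in range(n_reps):
        cfg = two_trait_config(seed + rep, m_snps=m_snps, n_ind=n_ind,
                               h2=h2, rg=rg)
        stats, truth = synthdata.simulate_sumstats(cfg)
        rho = float(truth.pheno_corr.iloc[0, 1])
        for trait in stats:
            est, se = estimate_h2(stats[trait])
            h2_est.append(est)
            h2_cover.append(abs(est - h2) <= 2 * se)
        r, se_r = estimate_rg(stats["A"], stats["B"], rho_s=rho)
        rg_est.append(r)
        rg_cover.append(abs(r - rg) <= 2 * se_r)
    return {
        "h2_true": h2, "rg_true": rg,
        "h2_mean": float(np.mean(h2_est)),
        "h2_bias": float(np.mean(h2_est) - h2),
        "h2_coverage": float(np.mean(h2_cover)),
        "rg_mean": float(np.mean(rg_est)),
        "rg_bias": float(np.mean(rg_est) - rg),
        "rg_coverage": float(np.mean(rg_cover)),
        "n_reps": n_reps,
    }


def tree_recovery(seed: int, n_seeds: int = 25, m_snps: int = 5_000,
                  n_ind: int = 20_000) -> dict[str, Any]:
    """Rebuild the 6-leaf/2-factor/1-super-factor tree from noisy rg.

    A replicate counts as recovered when the level-1 factors partition the
    leaves exactly as generated and a single top factor joins them.  The
    loading error is the largest absolute deviation from the generating
    loadings (0.8 at level 1, 0.7 at the top) among recovered replicates.
    """
    truth_partition = {frozenset({"a1", "a2", "a3"}),
                       frozenset({"b1", "b2", "b3"})}
    recovered, load_errs = [], []
    config = PipelineConfig()
    for rep in range(n_seeds):
        cfg = six_leaf_config(seed + 10_000 + rep, m_snps=m_snps, n_ind=n_ind)
        stats, truth = synthdata.simulate_sumstats(cfg)
        corr = build_corr_matrix(stats, rho_s=truth.pheno_corr)
        try:
            result = build_hierarchy(corr, stats, config,
                                     sampling_corr=truth.pheno_corr)
        except Exception:
            recovered.append(False)
            continue
        tree = result.tree
        level1 = [n for n in tree.factors() if n.level == 1]
        level2 = [n for n in tree.factors() if n.level == 2]
        ok = (
            len(level1) == 2 and len(level2) == 1
            and {tree.leaf_set(n.id) for n in level1} == truth_partition
            and set(level2[0].children) == {n.id for n in level1}
        )
        recovered.append(ok)
        if ok:
            errs = [abs(abs(lam) - 0.8)
                    for n in level1 for lam in n.loadings.values()]
            errs += [abs(abs(lam) - 0.7)
                     for lam in level2[0].loadings.values()]
            load_errs.extend(errs)
    return {
        "recovery_rate": float(np.mean(recovered)),
        "max_loading_error": float(np.max(load_errs)) if load_errs else float("nan"),
        "mean_loading_error": float(np.mean(load_errs)) if load_errs else float("nan"),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# effect-flow classification
# ---------------------------------------------------------------------------

def _single_snp_stats(beta_hat: np.ndarray, traits: list[str],
                      n_ind: int) -> dict[str, TraitSumStats]:
    from scipy import stats as sps
    se = 1.0 / np.sqrt(n_ind)
    out = {}
    for t, trait in enumerate(traits):
        z = beta_hat[t] / se
        out[trait] = TraitSumStats(trait, pd.DataFrame({
            "snp": ["rs1"], "chrom": ["1"], "pos": [1_000_000],
            "ea": ["A"], "oa": ["G"], "eaf": [0.5],
            "beta": [beta_hat[t]], "se": [se],
            "p": [max(2 * sps.norm.sf(abs(z)), 1e-300)], "n": [n_ind]}))
    return out


def classification_study(seed: int, n_sims: int = 100, n_ind: int = 20_000,
                         effect: float = 0.05) -> dict[str, Any]:
    """Direct vs mediated classification with the generating tree fixed.

    Per replicate a single sentinel's estimates across the six leaves are
    drawn from the full-overlap sampling model, factor and root marginals
    are formed by the factor GWAS combination, and the decomposition is run
    on the true tree.  Mediated pattern (factor-planted SNP): every child
    of the causal factor is classified as attenuated.  Direct pattern
    (leaf-planted SNP): the causal leaf is classified direct_only.
    """
    tree = six_leaf_truth_tree()
    base = six_leaf_config(seed, polygenic=False)
    pheno = synthdata.implied_pheno_corr(base)
    traits = list(pheno.columns)
    chol = np.linalg.cholesky(pheno.to_numpy())
    samp = node_sampling_corr(tree, pheno)
    rng = np.random.default_rng(seed)

    def run_one(target: str) -> list:
        true_marg = np.array([
            effect * base.tree.path_product(target, leaf) for leaf in traits])
        draw = true_marg + chol @ rng.standard_normal(len(traits)) / np.sqrt(n_ind)
        leaf_stats = _single_snp_stats(draw, traits, n_ind)
        factor_stats = _collect_factor_stats(tree, leaf_stats, pheno)
        estimates = {}
        for node, s in {**leaf_stats, **factor_stats}.items():
            estimates[node] = (float(s.table["beta"].iloc[0]),
                               float(s.table["se"].iloc[0]))
        return decompose_all(tree, "rs1", estimates, samp)

    mediated_ok, factor_direct, factor_cond_sig = [], [], []
    for _ in range(n_sims):
        decomp = {d.node: d for d in run_one("F1")}
        kids = ["a1", "a2", "a3"]
        mediated_ok.append(all(decomp[k].classification == "attenuated"
                               for k in kids))
        factor_direct.append(decomp["F1"].classification == "direct_only")
        factor_cond_sig.append(
            abs(decomp["F1"].conditional_beta / decomp["F1"].conditional_se) > 1.96)

    direct_ok = []
    for _ in range(n_sims):
        decomp = {d.node: d for d in run_one("a1")}
        direct_ok.append(decomp["a1"].classification == "direct_only")

    null_flagged = []
    for _ in range(n_sims):
        draw = chol @ rng.standard_normal(len(traits)) / np.sqrt(n_ind)
        leaf_stats = _single_snp_stats(draw, traits, n_ind)
        factor_stats = _collect_factor_stats(tree, leaf_stats, pheno)
        estimates = {n: (float(s.table["beta"].iloc[0]),
                         float(s.table["se"].iloc[0]))
                     for n, s in {**leaf_stats, **factor_stats}.items()}
        null_decomp = decompose_all(tree, "rs1", estimates, samp)
        within = [abs(d.conditional_beta) <= 2 * d.conditional_se
                  for d in null_decomp if d.conditional_beta is not None]
        null_flagged.append(float(np.mean(within)))

    return {
        "mediated_pattern_rate": float(np.mean(mediated_ok)),
        "factor_retains_direct_rate": float(np.mean(factor_direct)),
        "factor_conditional_significant_rate": float(np.mean(factor_cond_sig)),
        "direct_only_rate": float(np.mean(direct_ok)),
        "null_conditional_within_2se": float(np.mean(null_flagged)),
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_loci(positions: np.ndarray, pvalues: np.ndarray,
                     seed_p: float, gap: int) -> list[frozenset[int]]:
    """O(n^2) union-find grouping of seed SNPs: same locus iff linked by a
    chain of pairs at distance <= gap.  Independent of the sweep-line
    implementation in locusmap."""
    idx = [i for i in range(len(positions)) if pvalues[i] < seed_p]
    parent = {i: i for i in idx}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in idx:
        for b in idx:
            if a < b and abs(int(positions[a]) - int(positions[b])) <= gap:
                parent[find(a)] = find(b)
    groups: dict[int, set[int]] = {}
    for i in idx:
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def locus_oracle_check(seed: int, n_tracks: int = 100,
                       m_max: int = 2_000) -> dict[str, Any]:
    """Compare define_loci against the brute-force grouping on random
    p-value tracks; returns the fraction of tracks in exact agreement."""
    from scipy import stats as sps
    rng = np.random.default_rng(seed)
    agree = []
    for _ in range(n_tracks):
        m = int(rng.integers(50, m_max))
        pos = np.sort(rng.choice(np.arange(1, 50_000) * 1_000, m, replace=False))
        z = rng.standard_normal(m) * rng.uniform(1, 3)
        p = 2 * sps.norm.sf(np.abs(z))
        tab = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(m)], "chrom": "1", "pos": pos,
            "ea": "A", "oa": "G", "eaf": 0.3, "beta": z / 100.0,
            "se": 1 / 100.0, "p": np.clip(p, 1e-300, 1.0), "n": 10_000})
        stats = TraitSumStats("t", tab)
        loci = define_loci(stats, seed_p=1e-2, gap=250_000, sig_p=1e-4)
        got = [frozenset(int(s[2:]) for s in loc.snps["snp"]) for loc in loci]
        expect = brute_force_loci(pos, p, 1e-2, 250_000)
        agree.append(sorted(got, key=min) == expect)
    return {"agreement_rate": float(np.mean(agree)), "n_tracks": n_tracks}


def oracle_condition_subtree(lam: np.ndarray, child_effects, parent_effect,
                             v: np.ndarray, dv_corr: float):
    """Whitened ordinary-least-squares solution of the augmented system.

    Independent of the normal-equations solver used in effectflow: the
    weight matrix is factored by eigendecomposition and the whitened design
    solved with lstsq.
    """
    k = len(lam)
    y = np.array([b for b, _ in child_effects] + [parent_effect[0]], float)
    x = np.zeros((k + 1, k + 1))
    x[:k, 0] = dv_corr * np.asarray(lam)
    x[:k, 1:] = np.eye(k)
    x[k, 0] = dv_corr
    w = np.zeros((k + 1, k + 1))
    w[:k, :k] = v
    w[k, k] = parent_effect[1] ** 2
    vals, vecs = np.linalg.eigh(w)
    whiten = vecs @ np.diag(vals ** -0.5) @ vecs.T
    est, *_ = np.linalg.lstsq(whiten @ x, whiten @ y, rcond=None)
    cov = np.linalg.inv((whiten @ x).T @ (whiten @ x))
    return est, np.sqrt(np.diag(cov))


def brute_force_prioritize(sentinel: str, bundle, r2_strong: float = 0.8):
    """Plain-loop re-derivation of the smallest applicable prioritization
    rule; independent of the vectorized implementation in geneprior."""
    partners: dict[str, float] = {sentinel: 1.0}
    for _, row in bundle.ld.iterrows():
        if row["snp_a"] == sentinel:
            partners[row["snp_b"]] = max(partners.get(row["snp_b"], 0.0),
                                         float(row["r2"]))
        if row["snp_b"] == sentinel:
            partners[row["snp_a"]] = max(partners.get(row["snp_a"], 0.0),
                                         float(row["r2"]))
    csq = [(str(r["snp"]), str(r["gene"]), str(r["class"]))
           for _, r in bundle.consequences.iterrows()]

    def hits(classes, min_r2, strict):
        found = []
        for snp, gene, cls in csq:
            if cls not in classes or snp not in partners:
                continue
            r2 = partners[snp]
            if (r2 > min_r2) if strict else (r2 >= min_r2):
                found.append((gene, snp, r2))
        return found

    for rule, (classes, min_r2, strict) in enumerate([
            ({"nonsynonymous"}, r2_strong, True),
            ({"synonymous", "utr3", "utr5"}, r2_strong, True),
            ({"intronic"}, 1.0, False),
            ({"intronic"}, r2_strong, True)], start=1):
        found = hits(classes, min_r2, strict)
        if found:
            genes = {g for g, _, _ in found}
            return rule, genes
    pos_rows = bundle.snp_pos[bundle.snp_pos["snp"] == sentinel]
    if pos_rows.empty:
        return None, set()
    pos = int(pos_rows["pos"].iloc[0])
    best, best_d = set(), None
    for _, g in bundle.genes.iterrows():
        d = max(g["start"] - pos, pos - g["end"], 0)
        if best_d is None or d < best_d:
            best, best_d = {str(g["gene"])}, d
        elif d == best_d:
            best.add(str(g["gene"]))
    return 5, best


def prioritization_minimality_check(seed: int,
                                    n_bundles: int = 500) -> dict[str, Any]:
    """Check, on random annotation bundles, that the prioritizer always
    reports the smallest applicable rule and a gene that rule supports."""
    from .geneprior import prioritize
    rng = np.random.default_rng(seed)
    ok = []
    for _ in range(n_bundles):
        bundle, sentinel = synthdata.random_annotation_bundle(rng)
        got = prioritize(sentinel, bundle)
        rule, genes = brute_force_prioritize(sentinel, bundle)
        ok.append(got.rule == rule and got.gene in genes)
    return {"minimality_rate": float(np.mean(ok)), "n_bundles": n_bundles}


def conditional_oracle_check(seed: int, n_instances: int = 50) -> dict[str, Any]:
    """Max |difference| between the augmented-GLS solver and the whitened
    lstsq oracle over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(2, 6))
        lam = rng.uniform(0.3, 0.95, k)
        a = rng.standard_normal((k, k))
        v = a @ a.T / k + np.eye(k) * 0.1
        scale = rng.uniform(1e-4, 1e-2)
        v *= scale
        child = [(float(rng.normal(0, 0.05)), float(np.sqrt(v[i, i])))
                 for i in range(k)]
        parent = (float(rng.normal(0, 0.05)), float(rng.uniform(0.001, 0.02)))
        sub = SubTree(factor="F", children=[f"c{i}" for i in range(k)],
                      loadings=lam)
        p_est, c_ests = condition_subtree(sub, child, parent, v, dv_corr=0.99)
        est = np.array([p_est.beta] + [c.beta for c in c_ests])
        ses = np.array([p_est.se] + [c.se for c in c_ests])
        o_est, o_se = oracle_condition_subtree(lam, child, parent, v, 0.99)
        worst = max(worst, float(np.max(np.abs(est - o_est))),
                    float(np.max(np.abs(ses - o_se))))
    return {"max_abs_difference": worst, "n_instances": n_instances}
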