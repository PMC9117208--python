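"""End-to-end orchestration of the synthetic multi-trait GWAS pipeline.

Stage order mirrors the analysis design: synthetic data (or ingest) →
genetic correlations and the study-wide threshold → hierarchical factor
tree and factor GWAS → locus definition with sentinels → direct/mediated
effect decomposition → replication meta-analysis → gene prioritization.
Every numeric output is written as TSV/CSV/JSON under the run directory and
hashed into a machine-readable manifest, so re-running with the same seed
reproduces the manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import synthdata
from .config import DEFAULTS, PipelineConfig
from .effectflow import decompose_all, decomposition_table
from .gencorr import build_corr_matrix, effective_components
from .hierarchy import FactorTree, build_hierarchy, propagate_sampling_corr
from .io import tree_to_json, tree_to_newick, write_sumstats
from .locusmap import (associations_table, assign_sentinels, define_loci,
                       loci_to_bed, merge_overlapping)
from .replication import CohortResult, replication_report, sign_consistency_test
from .sumstats import TraitSumStats

__all__ = ["demo_sim_config", "run_pipeline", "node_sampling_corr"]

log = logging.getLogger(__name__)

_STAGE_DEPS = {
    "gencorr": ["synthdata"],
    "hierarchy": ["gencorr"],
    "locusmap": ["gencorr"],
    "effectflow": ["hierarchy", "locusmap"],
    "replication": ["locusmap"],
    "geneprior": ["locusmap"],
}


def demo_sim_config(seed: int = 0, n_individuals: int = 5_000,
                    n_snps: int = 2_000) -> synthdata.SimConfig:
    """Reference demo study: 8 leaf traits, two 3-leaf factors under one
    super-factor plus two free-standing traits, polygenic background and a
    few strong sentinel variants planted at factor and leaf level."""
    tree = {
        "id": "R", "children": [
            {"id": "FA", "loading": 0.7, "children": [
                {"id": "a1", "loading": 0.8}, {"id": "a2", "loading": 0.8},
                {"id": "a3", "loading": 0.8}]},
            {"id": "FB", "loading": 0.7, "children": [
                {"id": "b1", "loading": 0.8}, {"id": "b2", "loading": 0.8},
                {"id": "b3", "loading": 0.8}]},
        ],
    }
    spec = [tree, {"id": "c1"}, {"id": "c2"}]
    rng = np.random.default_rng(seed)
    background = synthdata.polygenic_effects(
        rng,
        {"R": 0.119, "FA": 0.042, "FB": 0.042,
         "a1": 0.036, "a2": 0.036, "a3": 0.036,
         "b1": 0.036, "b2": 0.036, "b3": 0.036,
         "c1": 0.08, "c2": 0.08},
        n_per_node=max(5, n_snps // 40), n_snps=n_snps)
    used = {idx for idx, _, _ in background}
    free = [i for i in range(n_snps) if i not in used]
    sentinels = [(free[len(free) // 10], "FA", 0.12),
                 (free[len(free) // 2], "b1", 0.12),
                 (free[-10], "R", 0.10)]
    return synthdata.SimConfig(
        n_individuals=n_individuals, n_snps=n_snps, tree_spec=spec,
        causal_snps=background + sentinels, likert_levels=0, seed=seed)


def node_sampling_corr(tree: FactorTree,
                       leaf_corr: pd.DataFrame) -> pd.DataFrame:
    """Sampling-error correlation among all tree nodes (leaves + factors),
    propagated bottom-up from the leaf phenotypic correlations."""
    r = leaf_corr.copy()
    for node in sorted(tree.factors(), key=lambda n: n.level):
        defs = {i: ([i], [1.0]) for i in r.columns}
        defs[node.id] = (list(node.children),
                         [node.loadings[c] for c in node.children])
        r = propagate_sampling_corr(r, defs)
    return r


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig = DEFAULTS,
    outdir: str | Path = "run",
    sim_config: synthdata.SimConfig | None = None,
    stats: Mapping[str, TraitSumStats] | None = None,
) -> dict[str, Any]:
    """Execute the enabled stages and return the run manifest.

    Either synthetic data is generated from ``sim_config`` (the demo study
    by default) or pre-loaded ``stats`` are ingested.  On stage failure a
    partial manifest naming the failed stage and cause is still written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    toggles = dict(config.stages)
    if stats is not None:
        toggles["synthdata"] = True   # ingest satisfies the data dependency
    for stage, deps in _STAGE_DEPS.items():
        if toggles.get(stage) and not all(toggles.get(d) for d in deps):
            missing = [d for d in deps if not toggles.get(d)]
            raise ValueError(
                f"stage {stage!r} requires disabled stage(s) {missing}")

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {k: v for k, v in config.to_dict().items()
                       if not isinstance(v, dict)},
        "stages": {}, "files": {}, "status": "ok",
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _hash_file(path)

    try:
        # -- data ----------------------------------------------------------
        if stats is None:
            sim = sim_config or demo_sim_config(config.seed)
            leaf_stats, truth = synthdata.simulate_sumstats(sim)
            pheno_corr = truth.pheno_corr
        else:
            leaf_stats = dict(stats)
            truth = None
            pheno_corr = pd.DataFrame(
                np.eye(len(leaf_stats)), index=list(leaf_stats),
                columns=list(leaf_stats))
        for trait, s in leaf_stats.items():
            write_sumstats(s, outdir / f"sumstats_{trait}.tsv")
            record("synthdata", outdir / f"sumstats_{trait}.tsv")
        if truth is not None:
            truth.true_beta.to_csv(outdir / "true_beta.tsv", sep="\t")
            truth.true_rg.to_csv(outdir / "true_rg.tsv", sep="\t")
            record("synthdata", outdir / "true_rg.tsv")
        manifest["stages"]["synthdata"] = {
            "traits": len(leaf_stats),
            "snps": next(iter(leaf_stats.values())).n_snps,
        }

        # -- genetic correlations -----------------------------------------
        corr = build_corr_matrix(leaf_stats, rho_s=pheno_corr,
                                 n_blocks=min(config.jackknife_blocks,
                                              next(iter(leaf_stats.values())).n_snps // 4))
        corr.write(outdir / "gencorr")
        mult = effective_components(corr, share=config.variance_share,
                                    alpha=config.genomewide_alpha)
        sig_p = mult.studywide_threshold
        manifest["stages"]["gencorr"] = {
            "traits_retained": len(corr.traits),
            "n_components": mult.n_components,
            "studywide_threshold": sig_p,
        }

        # -- hierarchy ------------------------------------------------------
        tree = None
        factor_stats: dict[str, TraitSumStats] = {}
        if toggles.get("hierarchy"):
            result = build_hierarchy(corr, leaf_stats, config,
                                     sampling_corr=pheno_corr)
            tree = result.tree
            factor_stats = result.factor_stats
            tree_to_json(tree, outdir / "tree.json")
            tree_to_newick(tree, outdir / "tree.nwk")
            record("hierarchy", outdir / "tree.json")
            manifest["stages"]["hierarchy"] = {
                "factors": len(tree.factors()),
                "levels": max((n.level for n in tree.factors()), default=0),
                "removed_items": len(result.report["removed_items"]),
            }

        # -- loci -----------------------------------------------------------
        loci = []
        all_stats = {**leaf_stats, **factor_stats}
        if toggles.get("locusmap"):
            per_trait = {t: define_loci(s, seed_p=config.seed_p,
                                        gap=config.locus_gap, sig_p=sig_p)
                         for t, s in all_stats.items()}
            loci = [l for l in merge_overlapping(per_trait) if l.significant]
            loci = [assign_sentinels(l, all_stats, r2_threshold=config.ld_r2)
                    for l in loci]
            loci_to_bed(loci).to_csv(outdir / "loci.bed", sep="\t",
                                     index=False, header=False)
            assoc = associations_table(loci)
            assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            record("locusmap", outdir / "associations.tsv")
            manifest["stages"]["locusmap"] = {
                "loci": len(loci),
                "associations": int(len(assoc)),
            }

        # -- effect decomposition ------------------------------------------
        if toggles.get("effectflow") and tree is not None and loci:
            samp = node_sampling_corr(tree, pheno_corr.loc[
                [l for l in pheno_corr.index if l in tree.nodes],
                [l for l in pheno_corr.columns if l in tree.nodes]])
            tables = []
            for loc in loci:
                for sub in loc.subloci:
                    sent = sub.sentinel
                    estimates = {}
                    for node_id in tree.nodes:
                        s = all_stats.get(node_id)
                        if s is None:
                            continue
                        row = s.indexed()
                        if sent in row.index:
                            estimates[node_id] = (float(row.loc[sent, "beta"]),
                                                  float(row.loc[sent, "se"]))
                    decomp = decompose_all(tree, sent, estimates, samp,
                                           dv_corr=config.dv_corr,
                                           alpha=config.clogg_alpha)
                    tables.append(decomposition_table(decomp))
            if tables:
                full = pd.concat(tables, ignore_index=True).drop_duplicates(
                    subset=["snp", "node"])
                full.to_csv(outdir / "decomposition.tsv", sep="\t", index=False)
                record("effectflow", outdir / "decomposition.tsv")
                direct = int((full["class"] == "direct_only").sum())
                manifest["stages"]["effectflow"] = {
                    "snp_node_pairs": int(len(full)),
                    "direct_only": direct,
                }

        # -- replication ----------------------------------------------------
        if toggles.get("replication") and loci and truth is not None:
            rep_sim = synthdata.SimConfig(
                n_individuals=max(config.min_n, 2_000),
                n_snps=sim.n_snps, tree_spec=sim.tree_spec,
                causal_snps=sim.causal_snps, likert_levels=0,
                seed=config.seed + 1_000_003)
            rep_stats, _ = synthdata.simulate_sumstats(rep_sim)
            cohorts = []
            for trait, s in rep_stats.items():
                nine = s.copy()   # emulate a cohort reporting on a 1..9 scale
                nine.table["beta"] *= 8.0
                nine.table["se"] *= 8.0
                cohorts.append(CohortResult(cohort="replica", stats=nine,
                                            scale_min=1, scale_max=9,
                                            n=rep_sim.n_individuals))
            assoc = associations_table(loci)
            disc = assoc.rename(columns={"top_snp": "snp"})[
                ["trait", "snp", "beta", "p"]]
            disc = disc[disc["trait"].isin(rep_stats)]
            report = replication_report(disc, cohorts, min_n=config.min_n,
                                        alpha=config.replication_alpha)
            report.to_csv(outdir / "replication.tsv", sep="\t", index=False)
            record("replication", outdir / "replication.tsv")
            tested = report[report["testable"]]
            k = int(tested["sign_consistent"].sum())
            n = int(len(tested))
            manifest["stages"]["replication"] = {
                "testable": n,
                "replicated": int(tested["replicated"].sum()),
                "sign_consistent": k,
                "sign_binomial_p": sign_consistency_test(k, n) if n else None,
            }

        # -- gene prioritization -------------------------------------------
        if toggles.get("geneprior") and loci:
            from .geneprior import prioritize_all
            sentinels = sorted({s.sentinel for l in loci for s in l.subloci})
            bundle, _expected = synthdata.make_annotation_fixture(
                config.seed, n_genes=len(sentinels), sentinels=sentinels)
            prior = prioritize_all(sentinels, bundle, r2_strong=config.ld_r2)
            prior.to_csv(outdir / "prioritized_genes.tsv", sep="\t", index=False)
            record("geneprior", outdir / "prioritized_genes.tsv")
            manifest["stages"]["geneprior"] = {
                "sentinels": len(sentinels),
                "rules": prior["rule"].value_counts().to_dict(),
            }
    except Exception as exc:   # partial-run manifest with the failure cause
        manifest["status"] = "failed"
        manifest["failure"] = {"stage": _last_stage(manifest), "cause": repr(exc)}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        raise

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest


def _last_stage(manifest: dict[str, Any]) -> str:
    done = list(manifest["stages"])
    order = ["synthdata", "gencorr", "hierarchy", "locusmap", "effectflow",
             "replication", "geneprior"]
    for stage in order:
        if stage not in done:
            return stage
    return "finalize"
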