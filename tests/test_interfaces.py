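"""File formats, configuration defaults, pipeline orchestration, CLI."""

import ast
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from treegwas.config import DEFAULTS, PipelineConfig
from treegwas.experiments import six_leaf_truth_tree
from treegwas.io import (read_sumstats, tree_from_json, tree_to_json,
                         tree_to_newick, write_sumstats)
from treegwas.pipeline import demo_sim_config, run_pipeline

SRC = Path(__file__).resolve().parents[1] / "src" / "treegwas"


class TestSumstatsIO:
    def test_round_trip(self, tmp_path, make_stats):
        stats = make_stats([0.1, -0.2, 0.05], 0.02, trait="apple")
        path = tmp_path / "apple.tsv"
        write_sumstats(stats, path)
        back = read_sumstats(path, trait="apple")
        pd.testing.assert_frame_equal(back.table, stats.table,
                                      check_dtype=False)

    def test_metal_style_dialect(self, tmp_path):
        path = tmp_path / "metal.tsv"
        path.write_text(
            "MarkerName\tChr\tBP\tAllele1\tAllele2\tFreq1\tEffect\tStdErr\t"
            "P-value\tN\n"
            "rs1\t1\t1000\tA\tG\t0.3\t0.10\t0.02\t1e-6\t5000\n"
            "rs2\t1\t2000\tA\tG\t0.4\t-0.05\t0.02\t0.01\t5000\n"
            "rs3\t2\t3000\tA\tG\t0.5\t0.00\t0.02\t0.9\t5000\n")
        stats = read_sumstats(path)
        assert stats.n_snps == 3
        assert stats.table["beta"].tolist() == [0.10, -0.05, 0.0]
        assert stats.table["chrom"].astype(str).tolist() == ["1", "1", "2"]

    def test_invalid_se_cites_line(self, tmp_path, make_stats):
        stats = make_stats([0.1, 0.2], 0.02)
        tab = stats.table.copy()
        tab.loc[1, "se"] = 0.0
        path = tmp_path / "bad.tsv"
        tab.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="line 3"):
            read_sumstats(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("snp\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValueError, match="se"):
            read_sumstats(path)


class TestTreeSerialization:
    def test_json_round_trip_is_byte_identical(self, tmp_path):
        tree = six_leaf_truth_tree()
        text1 = tree_to_json(tree)
        back = tree_from_json(text1)
        assert tree_to_json(back) == text1

    def test_newick_has_all_leaves_and_loadings(self):
        tree = six_leaf_truth_tree()
        nwk = tree_to_newick(tree)
        for leaf in tree.leaves():
            assert leaf in nwk
        assert nwk.count(",") == 5  # 6 leaves + 1 internal join at root
        assert "a1:0.8" in nwk and "F1:0.7" in nwk

    def test_newick_is_parseable_by_a_tree_library(self):
        import dendropy
        nwk = tree_to_newick(six_leaf_truth_tree())
        parsed = dendropy.Tree.get(data=nwk, schema="newick",
                                   suppress_internal_node_taxa=False)
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert labels == set(six_leaf_truth_tree().leaves())

    def test_cycle_rejected(self):
        from treegwas.hierarchy import FactorTree, Node
        tree = FactorTree(nodes={
            "a": Node(id="a", label="a", level=1, children=["b"],
                      loadings={"b": 0.5}),
            "b": Node(id="b", label="b", level=1, children=["a"],
                      loadings={"a": 0.5})}, roots=["a"])
        with pytest.raises(ValueError, match="cycle"):
            tree_to_json(tree)


class TestConfig:
    def test_defaults_match_study_constants(self):
        """Single source-of-truth table for every printed analysis constant."""
        expected = {
            "maf_min": 0.001,
            "genomewide_alpha": 5e-8,
            "variance_share": 0.95,
            "cfi_min": 0.9,
            "srmr_max": 0.1,
            "merge_rg": 0.9,
            "max_levels": 4,
            "seed_p": 1e-5,
            "locus_gap": 250_000,
            "dv_corr": 0.99,
            "clogg_alpha": 0.05,
            "replication_alpha": 0.05,
            "min_n": 10_000,
            "ld_r2": 0.8,
            "likert_levels": 9,
            "jackknife_blocks": 200,
        }
        cfg = PipelineConfig()
        for key, value in expected.items():
            assert getattr(cfg, key) == value, key

    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(seed=7, locus_gap=100_000)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = PipelineConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(dv_corr=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(variance_share=0.0)

    def test_no_module_hardcodes_thresholds(self):
        """Stage functions must default their thresholds to the config
        attributes, never to bare literals (checked on the AST of every
        threshold-bearing signature)."""
        watched = {
            ("locusmap.py", "define_loci"): {"seed_p", "gap"},
            ("geneprior.py", "prioritize"): {"r2_strong"},
            ("effectflow.py", "condition_subtree"): {"dv_corr"},
            ("effectflow.py", "decompose_all"): {"dv_corr", "alpha"},
            ("hierarchy.py", "fit_single_factor"): {"cfi_min", "srmr_max"},
            ("hierarchy.py", "merge_correlated_factors"): {"threshold"},
            ("replication.py", "test_replication"): {"alpha"},
            ("replication.py", "filter_testable"): {"min_n"},
            ("assoc.py", "run_trait_gwas"): {"maf_min"},
            ("gencorr.py", "effective_components"): {"share", "alpha"},
        }
        for (fname, func), params in watched.items():
            module = ast.parse((SRC / fname).read_text())
            fn = next(n for n in ast.walk(module)
                      if isinstance(n, ast.FunctionDef) and n.name == func)
            args = fn.args.args + fn.args.kwonlyargs
            defaults = list(fn.args.defaults) + list(fn.args.kw_defaults)
            named = dict(zip([a.arg for a in args[-len(defaults):]], defaults))
            for p in params:
                node = named[p]
                assert isinstance(node, ast.Attribute), \
                    f"{fname}:{func}({p}) has a literal default"
                assert node.value.id == "DEFAULTS"


class TestPipeline:
    def small_config(self, seed=5):
        return PipelineConfig(seed=seed, jackknife_blocks=100)

    def test_demo_run_end_to_end_and_deterministic(self, tmp_path):
        cfg = self.small_config()
        sim = demo_sim_config(cfg.seed, n_individuals=4_000, n_snps=1_500)
        m1 = run_pipeline(cfg, tmp_path / "r1", sim_config=sim)
        m2 = run_pipeline(cfg, tmp_path / "r2", sim_config=sim)
        assert m1["status"] == "ok"
        assert m1["files"] == m2["files"]  # identical content hashes
        assert m1["stages"]["locusmap"]["loci"] >= 1
        assert (tmp_path / "r1" / "manifest.json").exists()

    def test_dependency_gate(self, tmp_path):
        cfg = self.small_config()
        cfg.stages["locusmap"] = False
        with pytest.raises(ValueError, match="effectflow"):
            run_pipeline(cfg, tmp_path / "r")

    def test_stage_counters_recorded(self, tmp_path):
        cfg = self.small_config(seed=9)
        sim = demo_sim_config(9, n_individuals=4_000, n_snps=1_500)
        manifest = run_pipeline(cfg, tmp_path / "r", sim_config=sim)
        assert manifest["stages"]["synthdata"]["traits"] == 8
        assert manifest["stages"]["gencorr"]["n_components"] >= 1
        assert "studywide_threshold" in manifest["stages"]["gencorr"]


class TestCli:
    def test_run_subcommand(self, tmp_path):
        from click.testing import CliRunner
        from treegwas.cli import main
        runner = CliRunner()
        res = runner.invoke(main, ["run", "--seed", "3",
                                   "--out", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["status"] == "ok"

    def test_simulate_subcommand(self, tmp_path):
        from click.testing import CliRunner
        from treegwas.cli import main
        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "--seed", "2",
                                   "--out", str(tmp_path / "sim"),
                                   "--n-individuals", "500",
                                   "--n-snps", "400"])
        assert res.exit_code == 0, res.output
        files = list((tmp_path / "sim").glob("sumstats_*.tsv"))
        assert len(files) == 8
        back = read_sumstats(files[0])
        assert back.n_snps == 400
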