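"""File formats: summary-statistics TSV dialects, tree JSON/Newick, BED.

TSV is the canonical interchange for summary statistics, with a dialect
map translating foreign headers (METAL-style MarkerName/Effect/StdErr,
plink-style BP/A1, ...) onto the canonical columns.  Factor trees
round-trip losslessly through JSON (canonical key order) and export to
Newick with loadings as branch lengths for tree viewers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .hierarchy import FactorTree, Node
from .sumstats import REQUIRED_COLUMNS, TraitSumStats

__all__ = [
    "DEFAULT_ALIASES",
    "read_sumstats",
    "write_sumstats",
    "tree_to_json",
    "tree_from_json",
    "tree_to_newick",
]

#: Case-insensitive header aliases accepted without an explicit dialect.
DEFAULT_ALIASES: dict[str, str] = {
    "snp": "snp", "markername": "snp", "rsid": "snp", "id": "snp",
    "chrom": "chrom", "chr": "chrom", "chromosome": "chrom",
    "pos": "pos", "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "ea": "ea", "a1": "ea", "effect_allele": "ea", "allele1": "ea",
    "oa": "oa", "a2": "oa", "other_allele": "oa", "allele2": "oa",
    "eaf": "eaf", "freq": "eaf", "freq1": "eaf", "effect_allele_frequency": "eaf",
    "beta": "beta", "effect": "beta", "b": "beta",
    "se": "se", "stderr": "se", "standard_error": "se",
    "p": "p", "pval": "p", "p-value": "p", "p_value": "p", "pvalue": "p",
    "n": "n", "samplesize": "n", "neff": "n",
}


def read_sumstats(
    path: str | Path,
    trait: str | None = None,
    dialect: Mapping[str, str] | None = None,
) -> TraitSumStats:
    """Read a tab-separated summary-statistics file.

    ``dialect`` maps file headers to canonical names and takes precedence
    over the built-in aliases.  Validation errors cite 1-based data line
    numbers.  The trait id defaults to the file stem.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t")
    rename: dict[str, str] = {}
    for col in raw.columns:
        key = str(col)
        if dialect and key in dialect:
            rename[col] = dialect[key]
        elif key.lower() in DEFAULT_ALIASES:
            rename[col] = DEFAULT_ALIASES[key.lower()]
    tab = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing mandatory columns after dialect mapping: "
            f"{missing} (found {list(raw.columns)})")
    tab = tab[list(REQUIRED_COLUMNS)].copy()
    for col in ("snp", "chrom", "ea", "oa"):
        tab[col] = tab[col].astype(str)

    bad_rows: list[str] = []
    se = pd.to_numeric(tab["se"], errors="coerce")
    p = pd.to_numeric(tab["p"], errors="coerce")
    for idx in tab.index[(~(se > 0)) | (~((p > 0) & (p <= 1)))]:
        bad_rows.append(
            f"line {idx + 2}: se={tab.loc[idx, 'se']!r} p={tab.loc[idx, 'p']!r}")
    if bad_rows:
        raise ValueError(f"{path.name}: invalid rows:\n" + "\n".join(bad_rows[:20]))
    return TraitSumStats(trait or path.stem, tab.reset_index(drop=True))


def write_sumstats(stats: TraitSumStats, path: str | Path) -> None:
    stats.table[list(REQUIRED_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tree serialisation
# ---------------------------------------------------------------------------

def tree_to_json(tree: FactorTree, path: str | Path | None = None) -> str:
    """Lossless JSON with canonical key order; returns the text."""
    tree.validate()
    payload = {
        "roots": sorted(tree.roots),
        "nodes": {
            nid: {
                "label": n.label,
                "level": n.level,
                "children": list(n.children),
                "loadings": {k: n.loadings[k] for k in sorted(n.loadings)},
                "cfi": n.cfi,
                "srmr": n.srmr,
                "removed": sorted(n.removed),
                "flags": sorted(n.flags),
            }
            for nid, n in sorted(tree.nodes.items())
        },
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def tree_from_json(source: str | Path) -> FactorTree:
    text = Path(source).read_text() if isinstance(source, Path) or \
        (isinstance(source, str) and "\n" not in source and Path(source).exists()) \
        else str(source)
    payload = json.loads(text)
    tree = FactorTree()
    for nid, data in payload["nodes"].items():
        tree.nodes[nid] = Node(
            id=nid, label=data["label"], level=data["level"],
            children=list(data["children"]),
            loadings={k: float(v) for k, v in data["loadings"].items()},
            cfi=data["cfi"], srmr=data["srmr"],
            removed=list(data["removed"]), flags=list(data["flags"]))
    tree.roots = list(payload["roots"])
    tree.validate()
    return tree


def _newick_node(tree: FactorTree, node_id: str, length: float | None) -> str:
    node = tree.nodes[node_id]
    suffix = "" if length is None else f":{length:.6g}"
    if not node.children:
        return f"{node_id}{suffix}"
    parts = [_newick_node(tree, c, node.loadings.get(c, 0.0))
             for c in node.children]
    return f"({','.join(parts)}){node_id}{suffix}"


def tree_to_newick(tree: FactorTree, path: str | Path | None = None) -> str:
    """Newick topology with loadings encoded as branch lengths."""
    tree.validate()
    if len(tree.roots) == 1:
        text = _newick_node(tree, tree.roots[0], None) + ";"
    else:
        parts = [_newick_node(tree, r, 0.0) for r in sorted(tree.roots)]
        text = f"({','.join(parts)})root;"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
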