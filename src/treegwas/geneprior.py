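"""Ordered-rule gene prioritization for sentinel SNPs.

For each sentinel the most likely causal gene is chosen by the first
applicable of five rules, in order of importance:

1. the sentinel itself, or a partner in strong LD (r² > 0.8), is a
   non-synonymous variant in the gene;
2. the sentinel itself or a strong-LD partner is a coding variant in the
   gene in the wider sense (synonymous, 3'UTR or 5'UTR);
3. the sentinel is intronic in the gene, or in complete LD (r² = 1) with an
   intronic variant;
4. the sentinel is in strong LD (r² > 0.8) with an intronic variant in the
   gene;
5. otherwise, the gene closest to the sentinel position (distance 0 when
   inside the gene; ties broken by smaller start, then gene id).

Annotation comes from local tables (LD pairs, per-SNP functional
consequences, gene intervals) so the module is fully offline-testable.  If a
sentinel is absent from the annotation, its highest-r² proxy above the LD
threshold stands in; with no usable proxy the closest-gene rule is applied
to the sentinel itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import DEFAULTS

__all__ = ["AnnotationBundle", "PrioritizedGene", "prioritize", "prioritize_all"]

_NONSYN = {"nonsynonymous"}
_CODING = {"synonymous", "utr3", "utr5"}
_INTRONIC = {"intronic"}


@dataclass
class AnnotationBundle:
    """Local annotation tables used by the prioritizer.

    ``ld``: columns (snp_a, snp_b, r2), symmetric on lookup, self-LD is 1.
    ``consequences``: columns (snp, gene, class) with class one of
    nonsynonymous / synonymous / utr3 / utr5 / intronic / intergenic.
    ``genes``: columns (gene, chrom, start, end), 1-based inclusive.
    ``snp_pos``: columns (snp, chrom, pos) for the closest-gene rule.
    """

    ld: pd.DataFrame
    consequences: pd.DataFrame
    genes: pd.DataFrame
    snp_pos: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("empty gene set: prioritization undefined")
        bad = self.genes[self.genes["end"] < self.genes["start"]]
        if len(bad):
            raise ValueError(f"degenerate gene intervals: {bad['gene'].tolist()}")
        if len(self.ld) and not self.ld["r2"].between(0, 1).all():
            raise ValueError("LD r2 values must lie in [0, 1]")

    def partners(self, snp: str) -> pd.DataFrame:
        """All LD partners of ``snp`` (symmetric lookup), with r2."""
        if len(self.ld) == 0:
            return pd.DataFrame(columns=["snp", "r2"])
        a = self.ld[self.ld["snp_a"] == snp][["snp_b", "r2"]].rename(
            columns={"snp_b": "snp"})
        b = self.ld[self.ld["snp_b"] == snp][["snp_a", "r2"]].rename(
            columns={"snp_a": "snp"})
        both = pd.concat([a, b], ignore_index=True)
        return both.groupby("snp", as_index=False)["r2"].max()

    def position(self, snp: str) -> int | None:
        hit = self.snp_pos[self.snp_pos["snp"] == snp]
        return None if hit.empty else int(hit["pos"].iloc[0])


@dataclass
class PrioritizedGene:
    """Outcome for one sentinel: the gene, the (smallest applicable) rule,
    and the SNP/LD evidence that triggered it."""

    sentinel: str
    gene: str
    rule: int
    supporting_snp: str | None = None
    r2: float | None = None


def _candidates(sentinel: str, bundle: AnnotationBundle,
                r2_strong: float) -> pd.DataFrame:
    """Sentinel plus LD partners: columns (snp, r2), sentinel has r2=1."""
    rows = [(sentinel, 1.0)]
    for _, row in bundle.partners(sentinel).iterrows():
        rows.append((row["snp"], float(row["r2"])))
    return pd.DataFrame(rows, columns=["snp", "r2"])


def _best_hit(cands: pd.DataFrame, csq: pd.DataFrame,
              classes: set[str], min_r2: float,
              strict: bool) -> tuple[str, str, float] | None:
    """Highest-r2 (gene, snp, r2) among candidates with a consequence in
    ``classes``; ``strict`` demands r2 > min_r2, otherwise r2 >= min_r2."""
    keep = cands[cands["r2"] > min_r2] if strict else cands[cands["r2"] >= min_r2]
    if keep.empty:
        return None
    hits = keep.merge(csq[csq["class"].isin(classes)], on="snp")
    if hits.empty:
        return None
    hits = hits.sort_values(["r2", "gene", "snp"],
                            ascending=[False, True, True])
    top = hits.iloc[0]
    return str(top["gene"]), str(top["snp"]), float(top["r2"])


def closest_gene(pos: int, genes: pd.DataFrame) -> str:
    """Gene with minimal distance from ``pos`` to its interval (inside = 0);
    ties broken by smaller start, then lexicographic gene id."""
    g = genes.copy()
    g["dist"] = np.maximum.reduce([
        g["start"] - pos, pos - g["end"], np.zeros(len(g), dtype=int)])
    g = g.sort_values(["dist", "start", "gene"])
    return str(g.iloc[0]["gene"])


def prioritize(sentinel: str, bundle: AnnotationBundle,
               r2_strong: float = DEFAULTS.ld_r2) -> PrioritizedGene:
    """Apply the five ordered rules to one sentinel SNP."""
    cands = _candidates(sentinel, bundle, r2_strong)
    pos = bundle.position(sentinel)

    known = set(bundle.consequences["snp"]) | set(bundle.snp_pos["snp"])
    if sentinel not in known:
        # proxy fallback: best available strong-LD partner stands in
        proxies = cands[(cands["snp"] != sentinel) &
                        (cands["r2"] > r2_strong) &
                        (cands["snp"].isin(known))]
        if not proxies.empty:
            proxy = proxies.sort_values("r2", ascending=False).iloc[0]
            res = prioritize(str(proxy["snp"]), bundle, r2_strong)
            return PrioritizedGene(sentinel, res.gene, res.rule,
                                   res.supporting_snp, res.r2)

    csq = bundle.consequences
    hit = _best_hit(cands, csq, _NONSYN, r2_strong, strict=True)
    if hit:
        return PrioritizedGene(sentinel, hit[0], 1, hit[1], hit[2])
    hit = _best_hit(cands, csq, _CODING, r2_strong, strict=True)
    if hit:
        return PrioritizedGene(sentinel, hit[0], 2, hit[1], hit[2])
    hit = _best_hit(cands, csq, _INTRONIC, 1.0, strict=False)  # complete LD
    if hit:
        return PrioritizedGene(sentinel, hit[0], 3, hit[1], hit[2])
    hit = _best_hit(cands, csq, _INTRONIC, r2_strong, strict=True)
    if hit:
        return PrioritizedGene(sentinel, hit[0], 4, hit[1], hit[2])
    if pos is None:
        raise ValueError(
            f"sentinel {sentinel!r} has no position and no usable proxy; "
            "closest-gene rule cannot be applied")
    return PrioritizedGene(sentinel, closest_gene(pos, bundle.genes), 5)


def prioritize_all(sentinels: Iterable[str], bundle: AnnotationBundle,
                   r2_strong: float = DEFAULTS.ld_r2) -> pd.DataFrame:
    rows = []
    for s in sentinels:
        res = prioritize(s, bundle, r2_strong)
        rows.append((res.sentinel, res.gene, res.rule,
                     res.supporting_snp, res.r2))
    return pd.DataFrame(rows, columns=["sentinel", "gene", "rule",
                                       "supporting_snp", "r2"])
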