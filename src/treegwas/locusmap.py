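"""Genomic locus definition from multi-trait summary statistics.

Loci are defined by peak shape rather than fixed windows: all SNPs with
p below a seeding threshold (1e-5) are grouped per chromosome, and two
consecutive seed SNPs belong to different loci when they are strictly more
than 250 kb apart.  A locus is *significant* when at least one member SNP
passes the study-wide threshold.  Per-trait loci with overlapping
boundaries are merged (transitively) into multi-trait loci; each locus gets
a sentinel per shared-sentinel sub-locus, a deliberately simple stand-in
for co-localization that groups traits whose top SNPs coincide or are in
strong LD (r^2 > 0.8).

Coordinates are 1-based inclusive internally; BED export is 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .config import DEFAULTS
from .sumstats import TraitSumStats

__all__ = ["Locus", "SubLocus", "TraitAssociation", "define_loci",
           "merge_overlapping", "assign_sentinels", "loci_to_bed",
           "associations_table"]


@dataclass
class TraitAssociation:
    trait: str
    top_snp: str
    top_pos: int
    top_p: float
    beta: float
    se: float


@dataclass
class SubLocus:
    traits: list[str]
    sentinel: str


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    snps: pd.DataFrame                 # columns: snp, pos, p
    significant: bool
    traits: list[TraitAssociation] = field(default_factory=list)
    sentinel: str | None = None
    subloci: list[SubLocus] = field(default_factory=list)

    @property
    def min_p(self) -> float:
        return float(self.snps["p"].min())

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def define_loci(
    stats: TraitSumStats,
    seed_p: float = DEFAULTS.seed_p,
    gap: int = DEFAULTS.locus_gap,
    sig_p: float | None = None,
) -> list[Locus]:
    """Group sub-threshold SNPs into loci by the consecutive-gap rule.

    A gap of exactly ``gap`` base pairs does NOT split (strictly more than
    ``gap`` does).  ``sig_p`` is the study-wide significance threshold used
    to flag loci; defaults to the conventional genome-wide alpha.
    """
    if sig_p is None:
        sig_p = DEFAULTS.genomewide_alpha
    t = stats.table
    dup = t.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        conflicts = t.loc[dup].groupby(["chrom", "pos"])["snp"].nunique()
        if (conflicts > 1).any():
            raise ValueError(
                "duplicate (chrom, position) with conflicting SNP ids: "
                f"{conflicts[conflicts > 1].index.tolist()[:5]}")
    seeds = t[t["p"] < seed_p]
    loci: list[Locus] = []
    for chrom, sub in seeds.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > gap)[0] + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            members = sub.iloc[chunk]
            assoc = TraitAssociation(
                trait=stats.trait,
                top_snp=_top(members)["snp"],
                top_pos=int(_top(members)["pos"]),
                top_p=float(_top(members)["p"]),
                beta=float(_top(members)["beta"]),
                se=float(_top(members)["se"]),
            )
            loci.append(Locus(
                chrom=str(chrom),
                start=int(members["pos"].min()),
                end=int(members["pos"].max()),
                snps=members[["snp", "pos", "p"]].reset_index(drop=True),
                significant=bool((members["p"] < sig_p).any()),
                traits=[assoc] if bool((members["p"] < sig_p).any()) else [],
            ))
    return loci


def _top(members: pd.DataFrame) -> pd.Series:
    """Min-p row; ties broken by lower position."""
    best = members[members["p"] == members["p"].min()]
    return best.sort_values("pos").iloc[0]


def merge_overlapping(per_trait_loci: Mapping[str, Iterable[Locus]]) -> list[Locus]:
    """Merge loci with overlapping boundaries across traits (transitively).

    Each merged locus lists every trait with a significant association
    inside it; the merged interval is the union of member intervals and the
    member SNP table is the union of member SNPs.
    """
    flat: list[tuple[str, Locus]] = [
        (trait, loc) for trait, loci in per_trait_loci.items() for loc in loci]
    out: list[Locus] = []
    by_chrom: dict[str, list[tuple[str, Locus]]] = {}
    for trait, loc in flat:
        by_chrom.setdefault(loc.chrom, []).append((trait, loc))
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda e: (e[1].start, e[1].end))
        cluster: list[tuple[str, Locus]] = []
        cur_end = -1
        for trait, loc in entries:
            if cluster and loc.start > cur_end:
                out.append(_merge_cluster(chrom, cluster))
                cluster, cur_end = [], -1
            cluster.append((trait, loc))
            cur_end = max(cur_end, loc.end)
        if cluster:
            out.append(_merge_cluster(chrom, cluster))
    return out


def _merge_cluster(chrom: str, cluster: list[tuple[str, Locus]]) -> Locus:
    snps = pd.concat([loc.snps for _, loc in cluster], ignore_index=True)
    snps = (snps.sort_values(["pos", "p"])
            .drop_duplicates(subset=["snp"])
            .reset_index(drop=True))
    traits = [a for _, loc in cluster if loc.significant for a in loc.traits]
    return Locus(
        chrom=chrom,
        start=min(loc.start for _, loc in cluster),
        end=max(loc.end for _, loc in cluster),
        snps=snps,
        significant=any(loc.significant for _, loc in cluster),
        traits=sorted(traits, key=lambda a: (a.top_p, a.trait)),
    )


def assign_sentinels(
    locus: Locus,
    stats: Mapping[str, TraitSumStats],
    ld: pd.DataFrame | None = None,
    r2_threshold: float = DEFAULTS.ld_r2,
) -> Locus:
    """Choose per-trait top SNPs, group traits into shared-sentinel subloci.

    Traits fall in the same sub-locus when their top SNPs are identical or
    linked at r^2 > ``r2_threshold`` in the supplied LD table (transitive
    grouping); each sub-locus takes the top SNP of its smallest-p trait as
    sentinel.  This is a simplification standing where a co-localization
    backend would plug in.
    """
    if not locus.traits:
        raise ValueError("locus has no associated traits")
    missing = [a.trait for a in locus.traits if a.trait not in stats]
    if missing:
        raise ValueError(f"missing summary statistics for traits: {missing}")

    member_ids = set(locus.snps["snp"])
    tops: dict[str, tuple[str, float]] = {}
    for assoc in locus.traits:
        tab = stats[assoc.trait].table
        inside = tab[tab["snp"].isin(member_ids)]
        if inside.empty:
            raise ValueError(
                f"trait {assoc.trait!r} has no member SNPs inside the locus")
        top = _top(inside)
        tops[assoc.trait] = (str(top["snp"]), float(top["p"]))

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        if ld is None or ld.empty:
            return 0.0
        hit = ld[((ld["snp_a"] == a) & (ld["snp_b"] == b)) |
                 ((ld["snp_a"] == b) & (ld["snp_b"] == a))]
        return float(hit["r2"].max()) if len(hit) else 0.0

    g = nx.Graph()
    g.add_nodes_from(tops)
    traits = list(tops)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            if tops[a][0] == tops[b][0] or r2(tops[a][0], tops[b][0]) > r2_threshold:
                g.add_edge(a, b)

    subloci = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda t: (tops[t][1], t))
        subloci.append(SubLocus(traits=members, sentinel=tops[members[0]][0]))
    subloci.sort(key=lambda s: (min(tops[t][1] for t in s.traits), s.sentinel))
    locus.subloci = subloci
    locus.sentinel = subloci[0].sentinel if subloci else None
    return locus


def loci_to_bed(loci: Iterable[Locus]) -> pd.DataFrame:
    """BED (0-based half-open) with locus ids and -log10 minimum p."""
    rows = []
    for i, loc in enumerate(loci, start=1):
        rows.append((loc.chrom, loc.start - 1, loc.end,
                     f"locus{i}", -np.log10(loc.min_p)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def associations_table(loci: Iterable[Locus]) -> pd.DataFrame:
    """Long table: one row per (locus, trait) significant association."""
    rows = []
    for i, loc in enumerate(loci, start=1):
        for a in loc.traits:
            rows.append((f"locus{i}", loc.chrom, loc.start, loc.end,
                         a.trait, loc.sentinel, a.top_snp, a.beta, a.se, a.top_p))
    return pd.DataFrame(rows, columns=[
        "locus", "chrom", "start", "end", "trait", "sentinel",
        "top_snp", "beta", "se", "p"])
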