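"""Hierarchical factor model construction from genetic correlations.

The tree is grown level by level, mirroring hierarchical factor analysis on
summary statistics: (1) cluster the current traits on the dissimilarity
``sqrt(2 (1 - rg))`` with Ward's D2 linkage; (2) fit a single-factor model to
each multi-trait group by unweighted least squares on the correlation
matrix, gated on CFI > 0.9 and SRMR < 0.1, iteratively removing single
misfitting items; (3) run a factor-level GWAS for each retained factor as
the loading-weighted combination of its children's per-SNP effects;
(4) merge factors whose genetic correlation exceeds 0.9 and refit; then the
factor GWAS become the next level's inputs.  Iteration stops at
``max_levels`` or when the node count stops decreasing.

The traditional visual definition of groups is replaced by an automated
dendrogram cut (largest gap in merge heights by default; height or count
cuts are config-exposed) so runs are reproducible without a human step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.optimize import least_squares
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .config import DEFAULTS, PipelineConfig
from .gencorr import GeneticCorrMatrix, UndefinedCorrelationError, estimate_rg
from .sumstats import TraitSumStats, align_snps

__all__ = [
    "FactorFit",
    "Node",
    "FactorTree",
    "HierarchyError",
    "cluster_items",
    "fit_single_factor",
    "drop_misfit_items",
    "factor_gwas",
    "propagate_sampling_corr",
    "merge_correlated_factors",
    "build_hierarchy",
    "derived_drink_traits",
]

log = logging.getLogger(__name__)


class HierarchyError(RuntimeError):
    """Raised when no group ever passes the fit gates; carries diagnostics."""

    def __init__(self, msg: str, diagnostics: list[dict]):
        super().__init__(msg)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# tree containers
# ---------------------------------------------------------------------------

@dataclass
class Node:
    id: str
    label: str
    level: int
    children: list[str] = field(default_factory=list)
    loadings: dict[str, float] = field(default_factory=dict)
    cfi: float | None = None
    srmr: float | None = None
    removed: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def is_factor(self) -> bool:
        return bool(self.children)


@dataclass
class FactorTree:
    """Multi-level hierarchy of leaf traits and latent factors."""

    nodes: dict[str, Node] = field(default_factory=dict)
    roots: list[str] = field(default_factory=list)

    def validate(self) -> None:
        g = nx.DiGraph()
        for node in self.nodes.values():
            for child in node.children:
                if child not in self.nodes:
                    raise ValueError(f"node {node.id!r} has unknown child {child!r}")
                g.add_edge(node.id, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("factor tree contains a cycle")
        parents: dict[str, str] = {}
        for node in self.nodes.values():
            for child in node.children:
                if child in parents:
                    raise ValueError(
                        f"node {child!r} has two parents: {parents[child]!r}, {node.id!r}")
                parents[child] = node.id

    def parent_of(self, node_id: str) -> str | None:
        for node in self.nodes.values():
            if node_id in node.children:
                return node.id
        return None

    def leaves(self) -> list[str]:
        return [n.id for n in self.nodes.values() if not n.is_factor]

    def factors(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.is_factor]

    def leaf_set(self, node_id: str) -> frozenset[str]:
        node = self.nodes[node_id]
        if not node.is_factor:
            return frozenset([node.id])
        out: set[str] = set()
        for c in node.children:
            out |= self.leaf_set(c)
        return frozenset(out)

    def loading_path(self, ancestor: str, descendant: str) -> float:
        """Product of loadings from ``ancestor`` down to ``descendant``."""
        if ancestor == descendant:
            return 1.0
        node = self.nodes[ancestor]
        for child, lam in node.loadings.items():
            if child == descendant:
                return lam
            if descendant in self.leaf_set(child):
                return lam * self.loading_path(child, descendant)
        raise KeyError(f"{descendant!r} is not below {ancestor!r}")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_items(
    corr: GeneticCorrMatrix | pd.DataFrame,
    cut_height: float | None = None,
    n_groups: int | None = None,
) -> tuple[list[list[str]], np.ndarray]:
    """Ward-D2 clustering on sqrt(2 (1 - rg)) with a configurable cut.

    Default cut: the largest gap in the linkage merge heights (which yields
    all-singleton groups for uncorrelated traits, where the first merge
    height itself is the largest gap).  Returns (groups, linkage matrix).
    """
    if isinstance(corr, GeneticCorrMatrix):
        mat = corr.rg.copy()
    else:
        mat = corr.copy()
    items = [str(c) for c in mat.columns]
    arr = mat.to_numpy(dtype=float)
    if np.isnan(arr).any():
        bad = [(items[i], items[j]) for i, j in zip(*np.where(np.isnan(arr))) if i < j]
        raise ValueError(f"NaN correlations for pairs: {bad[:10]}")
    if len(items) == 1:
        return [[items[0]]], np.empty((0, 4))

    d = np.sqrt(np.maximum(2.0 * (1.0 - np.clip(arr, -1.0, 1.0)), 0.0))
    np.fill_diagonal(d, 0.0)
    z = sch.linkage(squareform(d, checks=False), method="ward")

    if n_groups is not None:
        labels = sch.fcluster(z, t=n_groups, criterion="maxclust")
    elif cut_height is not None:
        labels = sch.fcluster(z, t=cut_height, criterion="distance")
    else:
        heights = z[:, 2]
        if len(heights) == 1:
            labels = np.ones(len(items), dtype=int)
        elif heights[-1] - heights[0] < 0.05 * heights[-1]:
            # near-uniform merge heights: no cluster structure
            labels = np.arange(1, len(items) + 1)
        else:
            gaps = np.diff(heights)
            k = len(items) - (int(np.argmax(gaps)) + 1)
            labels = sch.fcluster(z, t=max(k, 1), criterion="maxclust")

    groups: dict[int, list[str]] = {}
    for item, lab in zip(items, labels):
        groups.setdefault(int(lab), []).append(item)
    return [groups[k] for k in sorted(groups)], z


# ---------------------------------------------------------------------------
# single-factor fit
# ---------------------------------------------------------------------------

@dataclass
class FactorFit:
    loadings: pd.Series
    cfi: float
    srmr: float
    fit_ok: bool
    discrepancy: float
    flags: list[str] = field(default_factory=list)


def _uls_residuals(lam: np.ndarray, r: np.ndarray, iu: tuple) -> np.ndarray:
    implied = np.outer(lam, lam)
    return (r - implied)[iu]


def fit_single_factor(
    corr_sub: pd.DataFrame | np.ndarray,
    n_eff: float,
    cfi_min: float = DEFAULTS.cfi_min,
    srmr_max: float = DEFAULTS.srmr_max,
) -> FactorFit:
    """ULS single-factor fit of a correlation sub-matrix.

    Minimizes sum over unique off-diagonal elements of (r_ij - l_i l_j)^2.
    CFI uses the ULS discrepancy scaled by the effective sample size against
    the independence model; SRMR is the RMS of the off-diagonal residuals.
    Two-trait groups use the equal-loading sqrt(r) convention (df = 0,
    flagged under-identified).  The sign is fixed so the largest-magnitude
    loading is positive.
    """
    if isinstance(corr_sub, pd.DataFrame):
        names = [str(c) for c in corr_sub.columns]
        r = corr_sub.to_numpy(dtype=float)
    else:
        r = np.asarray(corr_sub, float)
        names = [f"t{i}" for i in range(r.shape[0])]
    p = r.shape[0]
    if p < 2:
        raise ValueError("a factor needs at least two indicators")

    flags: list[str] = []
    if p == 2:
        rr = float(np.clip(r[0, 1], -1.0, 1.0))
        lam = np.array([np.sqrt(abs(rr)), np.sign(rr) * np.sqrt(abs(rr))]) \
            if rr != 0 else np.zeros(2)
        flags.append("underidentified_pair")
        srmr, cfi, disc = 0.0, 1.0, 0.0
    else:
        iu = np.triu_indices(p, k=1)
        e, v = np.linalg.eigh(r)
        starts = [v[:, -1] * np.sqrt(max(e[-1], 0.0) * (1 - 1 / p)),
                  np.full(p, 0.5)]
        rng = np.random.default_rng(0)
        starts.append(rng.uniform(-0.9, 0.9, size=p))
        best = None
        for x0 in starts:
            sol = least_squares(_uls_residuals, x0, args=(r, iu), method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.isfinite(best.cost):
            raise RuntimeError("single-factor ULS fit failed to converge")
        lam = best.x
        resid = _uls_residuals(lam, r, iu)
        disc = float(np.sum(resid ** 2))
        srmr = float(np.sqrt(np.mean(resid ** 2)))
        f0 = float(np.sum(r[iu] ** 2))
        df_m = p * (p - 1) / 2 - p
        df_0 = p * (p - 1) / 2
        chi_m = max(n_eff - 1, 1.0) * disc
        chi_0 = max(n_eff - 1, 1.0) * f0
        denom = max(chi_0 - df_0, chi_m - df_m, 0.0)
        cfi = 1.0 if denom == 0 else 1.0 - max(chi_m - df_m, 0.0) / denom

    if lam[np.argmax(np.abs(lam))] < 0:
        lam = -lam
    # a common factor needs at least two salient indicators; with fewer the
    # off-diagonal fit is vacuous (e.g. identity input, where any single
    # non-zero loading has zero cost) and the solution is canonicalized to 0
    if np.sum(np.abs(lam) > 0.1) < 2:
        flags.append("degenerate")
        if p > 2:
            lam = np.zeros(p)
    if np.max(np.abs(lam)) > 1.05:
        flags.append("loading_out_of_range")

    fit_ok = (cfi > cfi_min) and (srmr < srmr_max)
    return FactorFit(pd.Series(lam, index=names, name="loading"),
                     float(cfi), float(srmr), bool(fit_ok), disc, flags)


def drop_misfit_items(
    group: Sequence[str],
    corr: pd.DataFrame,
    n_eff: float,
    cfi_min: float = DEFAULTS.cfi_min,
    srmr_max: float = DEFAULTS.srmr_max,
) -> tuple[list[str] | None, FactorFit | None, list[str], list[dict]]:
    """Iteratively remove the worst-misfitting item until the gates pass.

    The removed item is the one with the largest mean absolute correlation
    residual.  Returns (retained group, fit, removed items, audit trail);
    the group is ``None`` when it dissolves (fewer than 3 items left while
    still failing).
    """
    current = list(group)
    removed: list[str] = []
    audit: list[dict] = []
    while True:
        sub = corr.loc[current, current]
        fit = fit_single_factor(sub, n_eff, cfi_min, srmr_max)
        ok = fit.fit_ok and "degenerate" not in fit.flags
        audit.append({"group": list(current), "cfi": fit.cfi,
                      "srmr": fit.srmr, "discrepancy": fit.discrepancy,
                      "ok": ok})
        if ok:
            return current, fit, removed, audit
        if len(current) <= 3:
            audit.append({"dissolved": list(current)})
            log.info("group dissolved after removals: %s", current)
            return None, None, removed + current, audit
        lam = fit.loadings.to_numpy()
        resid = np.abs(sub.to_numpy() - np.outer(lam, lam))
        np.fill_diagonal(resid, 0.0)
        worst = current[int(np.argmax(resid.mean(axis=1)))]
        removed.append(worst)
        audit.append({"removed": worst})
        current = [c for c in current if c != worst]


# ---------------------------------------------------------------------------
# factor-level GWAS
# ---------------------------------------------------------------------------

def factor_gwas(
    children: Sequence[TraitSumStats],
    loadings: Mapping[str, float] | pd.Series,
    sampling_corr: pd.DataFrame,
    factor_id: str = "F",
) -> TraitSumStats:
    """Per-SNP effect on a latent factor as the loading-weighted combination
    of the children's effects.

        beta_F = sum_i l_i beta_i / sum_i l_i^2
        var_F  = (l' V l) / (sum_i l_i^2)^2

    where V is the per-SNP cross-trait sampling covariance of the child
    estimates, built from ``sampling_corr`` and the per-SNP standard errors.
    The factor's ``n`` column is the effective 1/se^2 so downstream moment
    estimators calibrate correctly on the factor's unit-variance scale.
    """
    lam = pd.Series(loadings, dtype=float)
    kids = align_snps(children)
    order = [k.trait for k in kids]
    lam = lam.loc[order]
    if np.allclose(lam, 0.0):
        raise ValueError("all loadings are zero: factor effect undefined")
    rho = sampling_corr.loc[order, order].to_numpy(dtype=float)

    betas = np.column_stack([np.asarray(k.table["beta"], float) for k in kids])
    ses = np.column_stack([np.asarray(k.table["se"], float) for k in kids])
    lvec = lam.to_numpy()
    denom = float(np.sum(lvec ** 2))
    beta_f = betas @ lvec / denom
    w = ses * lvec[None, :]
    var_f = np.einsum("mi,ij,mj->m", w, rho, w) / denom ** 2
    se_f = np.sqrt(var_f)
    z = beta_f / se_f
    p = np.clip(2 * sps.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)

    tab = kids[0].table[["snp", "chrom", "pos", "ea", "oa", "eaf"]].copy()
    tab["beta"] = beta_f
    tab["se"] = se_f
    tab["p"] = p
    tab["n"] = 1.0 / var_f
    return TraitSumStats(factor_id, tab, provenance={
        "factor": factor_id,
        "children": order,
        "loadings": {t: float(v) for t, v in lam.items()},
    })


def propagate_sampling_corr(
    corr: pd.DataFrame,
    defs: Mapping[str, tuple[Sequence[str], Sequence[float]]],
) -> pd.DataFrame:
    """Sampling-error correlation among derived nodes.

    ``defs`` maps each new node to (member ids, weights); a pass-through
    item is simply ``([item], [1.0])``.  The derived correlation is
    w_a' R_ab w_b normalized by the member-level quadratic forms.
    """
    names = list(defs)
    k = len(names)
    out = np.eye(k)
    def quad(a: str, b: str) -> float:
        ma, wa = defs[a]
        mb, wb = defs[b]
        block = corr.loc[list(ma), list(mb)].to_numpy(dtype=float)
        return float(np.asarray(wa, float) @ block @ np.asarray(wb, float))
    for i, a in enumerate(names):
        for j in range(i + 1, k):
            b = names[j]
            val = quad(a, b) / np.sqrt(quad(a, a) * quad(b, b))
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=names, columns=names)


def merge_correlated_factors(
    rg: pd.DataFrame,
    threshold: float = DEFAULTS.merge_rg,
) -> list[set[str]]:
    """Connected components of the rg > threshold graph over factors."""
    g = nx.Graph()
    g.add_nodes_from(rg.columns)
    for i, a in enumerate(rg.columns):
        for b in rg.columns[i + 1:]:
            if rg.loc[a, b] > threshold:
                g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# the level iteration
# ---------------------------------------------------------------------------

@dataclass
class HierarchyResult:
    tree: FactorTree
    factor_stats: dict[str, TraitSumStats]
    report: dict[str, Any]


def build_hierarchy(
    corr: GeneticCorrMatrix,
    stats: Mapping[str, TraitSumStats],
    config: PipelineConfig = DEFAULTS,
    sampling_corr: pd.DataFrame | None = None,
) -> HierarchyResult:
    """Grow the multi-level factor tree; see the module docstring.

    ``sampling_corr`` is the cross-trait sampling-error correlation of the
    leaf estimates (the phenotypic correlation under full sample overlap);
    defaults to the rho_s offsets recorded in ``corr``.
    """
    if len(corr.traits) < 4:
        raise ValueError("hierarchy construction needs at least 4 traits")
    if sampling_corr is None:
        sampling_corr = corr.rho_s

    tree = FactorTree()
    for t in corr.traits:
        tree.nodes[t] = Node(id=t, label=t, level=0)

    cur_ids = list(corr.traits)
    cur_stats = {t: stats[t] for t in cur_ids}
    cur_corr = corr
    cur_samp = sampling_corr.loc[cur_ids, cur_ids]
    report: dict[str, Any] = {"levels": [], "removed_items": [],
                              "diagnostics": []}
    attempted_any = False
    retained_any = False

    for level in range(1, config.max_levels + 1):
        if len(cur_ids) < 2:
            break
        rg_df = cur_corr.rg.loc[cur_ids, cur_ids]
        if len(cur_ids) == 2:
            if abs(rg_df.iloc[0, 1]) <= config.pair_min_abs_rg:
                break
            groups = [list(cur_ids)]
        else:
            groups, _ = cluster_items(cur_corr)
        multi = [g for g in groups if len(g) >= 2]
        single = [g[0] for g in groups if len(g) == 1]
        if not multi:
            break
        attempted_any = True

        level_info: dict[str, Any] = {"level": level, "groups": groups,
                                      "factors": [], "passthrough": single}
        defs: dict[str, tuple[list[str], list[float]]] = {}
        new_stats: dict[str, TraitSumStats] = {}
        factor_members: dict[str, tuple[list[str], FactorFit]] = {}
        counter = 0
        for g in multi:
            n_eff = float(np.mean([cur_stats[t].mean_n for t in g]))
            if len(g) == 2:
                if abs(rg_df.loc[g[0], g[1]]) <= config.pair_min_abs_rg:
                    single.extend(g)
                    level_info.setdefault("dissolved", []).append(list(g))
                    continue
                fit = fit_single_factor(rg_df.loc[g, g], n_eff,
                                        config.cfi_min, config.srmr_max)
                kept, removed = list(g), []
            else:
                kept, fit, removed, audit = drop_misfit_items(
                    g, rg_df, n_eff, config.cfi_min, config.srmr_max)
                report["diagnostics"].extend(audit)
                if kept is None:
                    single.extend(g)
                    level_info.setdefault("dissolved", []).append(list(g))
                    continue
                report["removed_items"].extend(removed)
            counter += 1
            fid = f"F{level}_{counter}"
            factor_members[fid] = (kept, fit)
            level_info["factors"].append(fid)
            node = Node(id=fid, label=f"F-{fid}", level=level,
                        children=list(kept),
                        loadings={t: float(v) for t, v in fit.loadings.items()},
                        cfi=fit.cfi, srmr=fit.srmr, removed=removed,
                        flags=list(fit.flags))
            tree.nodes[fid] = node

        if not factor_members:
            if level == 1 and not retained_any:
                raise HierarchyError(
                    "no group passed the single-factor fit gates",
                    report["diagnostics"])
            break
        retained_any = True

        # factor GWAS for the retained factors
        for fid, (kept, fit) in factor_members.items():
            fs = factor_gwas([cur_stats[t] for t in kept], fit.loadings,
                             cur_samp.loc[kept, kept], factor_id=fid)
            new_stats[fid] = fs
            defs[fid] = (list(kept), [float(fit.loadings[t]) for t in kept])

        # merge factors with rg above the threshold, refit over the union
        fids = list(factor_members)
        if len(fids) >= 2:
            samp_f = propagate_sampling_corr(cur_samp, defs)
            rg_f = pd.DataFrame(np.eye(len(fids)), index=fids, columns=fids)
            for i, a in enumerate(fids):
                for b in fids[i + 1:]:
                    try:
                        r, _ = estimate_rg(new_stats[a], new_stats[b],
                                           rho_s=float(samp_f.loc[a, b]),
                                           n_blocks=min(config.jackknife_blocks,
                                                        new_stats[a].n_snps // 2))
                    except UndefinedCorrelationError:
                        r = 0.0
                    rg_f.loc[a, b] = rg_f.loc[b, a] = r
            for comp in merge_correlated_factors(rg_f, config.merge_rg):
                if len(comp) < 2:
                    continue
                members = sorted({m for f in comp for m in factor_members[f][0]})
                n_eff = float(np.mean([cur_stats[t].mean_n for t in members]))
                fit = fit_single_factor(rg_df.loc[members, members], n_eff,
                                        config.cfi_min, config.srmr_max)
                counter += 1
                fid = f"F{level}_{counter}m"
                level_info.setdefault("merged", []).append(
                    {"from": sorted(comp), "into": fid})
                for old in comp:
                    del tree.nodes[old]
                    del new_stats[old]
                    del defs[old]
                    del factor_members[old]
                tree.nodes[fid] = Node(
                    id=fid, label=f"F-{fid}", level=level,
                    children=list(members),
                    loadings={t: float(v) for t, v in fit.loadings.items()},
                    cfi=fit.cfi, srmr=fit.srmr, flags=list(fit.flags) + ["merged"])
                factor_members[fid] = (members, fit)
                new_stats[fid] = factor_gwas(
                    [cur_stats[t] for t in members], fit.loadings,
                    cur_samp.loc[members, members], factor_id=fid)
                defs[fid] = (list(members),
                             [float(fit.loadings[t]) for t in members])
                level_info["factors"] = [f for f in level_info["factors"]
                                         if f not in comp] + [fid]

        report["levels"].append(level_info)

        next_ids = list(factor_members) + [s for s in single]
        if len(next_ids) >= len(cur_ids):
            cur_ids = next_ids
            cur_stats = {**{f: new_stats[f] for f in factor_members},
                         **{s: cur_stats[s] for s in single}}
            break
        for s in single:
            new_stats[s] = cur_stats[s]
            defs[s] = ([s], [1.0])
        cur_samp = propagate_sampling_corr(cur_samp, defs)
        cur_stats = {i: new_stats[i] for i in next_ids}
        cur_ids = next_ids
        if len(cur_ids) < 2:
            break
        from .gencorr import build_corr_matrix
        cur_corr = build_corr_matrix(cur_stats, rho_s=cur_samp,
                                     n_blocks=min(config.jackknife_blocks,
                                                  max(2, min(s.n_snps for s in cur_stats.values()) // 2)))
        missing = [t for t in cur_ids if t not in cur_corr.traits]
        if missing:  # a factor with non-positive h2 cannot seed another level
            log.warning("stopping: no usable h2 for %s", missing)
            break
        cur_corr.rg = cur_corr.rg.loc[cur_ids, cur_ids]

    tree.roots = [n for n in tree.nodes if tree.parent_of(n) is None]
    tree.validate()
    all_factor_stats = {fid: s for fid, s in _collect_factor_stats(tree, stats,
                                                                   sampling_corr).items()}
    return HierarchyResult(tree=tree, factor_stats=all_factor_stats,
                           report=report)


def _collect_factor_stats(
    tree: FactorTree,
    leaf_stats: Mapping[str, TraitSumStats],
    sampling_corr: pd.DataFrame,
) -> dict[str, TraitSumStats]:
    """Recompute factor summary statistics bottom-up over the final tree.

    Rebuilding from the final topology (rather than keeping per-level
    intermediates) guarantees the stored statistics match the tree actually
    returned, including merged factors.
    """
    stats: dict[str, TraitSumStats] = dict(leaf_stats)
    samp = sampling_corr.copy()
    factors = sorted(tree.factors(), key=lambda n: n.level)
    for node in factors:
        fs = factor_gwas([stats[c] for c in node.children], node.loadings,
                         samp.loc[node.children, node.children],
                         factor_id=node.id)
        stats[node.id] = fs
        defs = {i: ([i], [1.0]) for i in samp.columns}
        defs[node.id] = (list(node.children),
                         [node.loadings[c] for c in node.children])
        samp = propagate_sampling_corr(samp, defs)
    return {n.id: stats[n.id] for n in factors}


def derived_drink_traits(pheno: pd.DataFrame, sweetened: str, unsweetened: str,
                         prefix: str) -> pd.DataFrame:
    """Max-score and sweetened-minus-unsweetened derived phenotype columns.

    Mirrors the derived coffee/tea measures: the maximum reflects liking for
    the drink in its preferred form, the difference reflects polarization
    toward the sweetened variant.
    """
    out = pd.DataFrame(index=pheno.index)
    out[f"{prefix}_max"] = pheno[[sweetened, unsweetened]].max(axis=1)
    out[f"{prefix}_diff"] = pheno[sweetened] - pheno[unsweetened]
    return out
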