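"""Direct versus factor-mediated SNP effect decomposition.

The hierarchical model is split into one-factor sub-trees (a factor plus its
children, loadings frozen from tree construction).  For each sub-tree the
SNP's marginal estimates on the children and on the factor are re-fit
jointly: the factor estimate is treated as an extra observed equation
through a dummy latent variable correlated 0.99 with the factor, which makes
the system exactly identified.  In matrix form, with k children,

    observations  y = (b^_1, ..., b^_k, b^_L)
    unknowns      (b_L, b_1, ..., b_k)
    design        child i row:  dv_corr * lambda_i  on b_L,  1 on b_i
                  factor row:   dv_corr             on b_L
    weights       blockdiag(V, se_L^2)

solved by generalized least squares; V is the cross-trait sampling
covariance of the child estimates.  Intermediate factors receive two
conditional estimates (one as a child of their parent's sub-tree, one as the
parent of their own); the one with the smaller |Z| is kept, the rationale
being that conditioning on a true mediator shrinks the effect.  Each node's
marginal and selected conditional estimate are then compared with the Clogg
Z-test,

    Z = (b1 - b2) / sqrt(SE1^2 + SE2^2),

and a node is classified *direct_only* when the two do not differ
(two-sided p > 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULTS
from .hierarchy import FactorTree, Node

__all__ = [
    "SubTree",
    "ConditionalEstimate",
    "EffectDecomposition",
    "split_subtrees",
    "condition_subtree",
    "select_min_z",
    "clogg_test",
    "decompose_all",
    "decomposition_table",
]


@dataclass
class SubTree:
    """A factor with its immediate children and frozen loadings."""

    factor: str
    children: list[str]
    loadings: np.ndarray


@dataclass
class ConditionalEstimate:
    beta: float
    se: float
    role: str          # "child" (in the parent's sub-tree) or "parent"
    subtree: str

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class EffectDecomposition:
    snp: str
    node: str
    marginal_beta: float | None
    marginal_se: float | None
    conditional_beta: float | None
    conditional_se: float | None
    clogg_z: float | None
    clogg_p: float | None
    classification: str            # direct_only | attenuated | na
    provenance: dict = field(default_factory=dict)


def split_subtrees(tree: FactorTree) -> list[SubTree]:
    """One sub-tree per factor; loadings copied (frozen) from the tree."""
    out = []
    for node in sorted(tree.factors(), key=lambda n: (n.level, n.id)):
        out.append(SubTree(
            factor=node.id,
            children=list(node.children),
            loadings=np.array([node.loadings[c] for c in node.children], float),
        ))
    return out


def condition_subtree(
    subtree: SubTree,
    child_effects: Sequence[tuple[float, float]],
    parent_effect: tuple[float, float],
    sampling_cov: np.ndarray,
    dv_corr: float = DEFAULTS.dv_corr,
) -> tuple[ConditionalEstimate, list[ConditionalEstimate]]:
    """Augmented GLS fit of one sub-tree; see the module docstring.

    Returns the factor's conditional (parent-role) estimate and one
    child-role conditional estimate per child.  ``dv_corr`` must be strictly
    inside (0, 1): at 1 the dummy latent coincides with the factor and the
    structural model it emulates is under-identified.
    """
    if not 0.0 < dv_corr < 1.0:
        raise ValueError(
            f"dv_corr must be in (0, 1); at {dv_corr} the dummy latent is "
            "collinear with the factor (rank-deficient model)")
    lam = np.asarray(subtree.loadings, float)
    k = len(lam)
    if len(child_effects) != k:
        raise ValueError("child effect count does not match loadings")
    betas = np.array([b for b, _ in child_effects], float)
    ses = np.array([s for _, s in child_effects], float)
    beta_l, se_l = parent_effect
    v = np.asarray(sampling_cov, float)
    if v.shape != (k, k):
        raise ValueError("sampling covariance has wrong shape")

    y = np.concatenate([betas, [beta_l]])
    x = np.zeros((k + 1, k + 1))
    x[:k, 0] = dv_corr * lam
    x[:k, 1:] = np.eye(k)
    x[k, 0] = dv_corr
    w = np.zeros((k + 1, k + 1))
    w[:k, :k] = v
    w[k, k] = se_l ** 2

    wi = np.linalg.inv(w)
    xtwx = x.T @ wi @ x
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular weighted design (condition number {cond:.3g})")
    cov = np.linalg.inv(xtwx)
    est = cov @ x.T @ wi @ y

    parent = ConditionalEstimate(float(est[0]), float(np.sqrt(cov[0, 0])),
                                 role="parent", subtree=subtree.factor)
    children = [
        ConditionalEstimate(float(est[1 + i]), float(np.sqrt(cov[1 + i, 1 + i])),
                            role="child", subtree=subtree.factor)
        for i in range(k)
    ]
    return parent, children


def select_min_z(
    estimates: Sequence[ConditionalEstimate],
) -> tuple[ConditionalEstimate, bool]:
    """Pick the conditional estimate with the smallest |Z|.

    Exact ties are resolved toward the child-role estimate (the sub-tree in
    which the node is conditioned on its own parent); returns the chosen
    estimate and a flag marking a tie.
    """
    ests = [e for e in estimates if e is not None]
    if not ests:
        raise ValueError("no conditional estimates supplied")
    if len(ests) == 1:
        return ests[0], False
    zs = [abs(e.z) for e in ests]
    tie = abs(zs[0] - zs[1]) < 1e-15
    if tie:
        chosen = next((e for e in ests if e.role == "child"), ests[0])
        return chosen, True
    return ests[int(np.argmin(zs))], False


def clogg_test(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Z-test for the difference between two regression coefficients."""
    if se1 <= 0 and se2 <= 0:
        raise ValueError("both standard errors are zero: Z undefined")
    z = (b1 - b2) / np.sqrt(se1 ** 2 + se2 ** 2)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def decompose_all(
    tree: FactorTree,
    snp: str,
    node_estimates: Mapping[str, tuple[float, float]],
    node_sampling_corr: pd.DataFrame,
    dv_corr: float = DEFAULTS.dv_corr,
    alpha: float = DEFAULTS.clogg_alpha,
) -> list[EffectDecomposition]:
    """Classify one sentinel SNP's effect on every node of the model.

    ``node_estimates`` maps node id to the marginal (beta, se): leaf
    marginals from the trait scans, factor marginals from the factor GWAS.
    ``node_sampling_corr`` is the sampling-error correlation among all node
    estimates (propagated from the leaf phenotypic correlations).
    Sub-trees are evaluated bottom-up; intermediate factors keep their
    min-|Z| conditional.  Nodes lacking a marginal estimate are reported as
    ``na``.
    """
    conditionals: dict[str, list[ConditionalEstimate]] = {n: [] for n in tree.nodes}
    skipped: set[str] = set()

    for sub in split_subtrees(tree):
        needed = sub.children + [sub.factor]
        if any(n not in node_estimates for n in needed):
            skipped.update(n for n in needed if n not in node_estimates)
            continue
        ses = np.array([node_estimates[c][1] for c in sub.children])
        rho = node_sampling_corr.loc[sub.children, sub.children].to_numpy(float)
        v = rho * np.outer(ses, ses)
        parent_est, child_ests = condition_subtree(
            sub,
            [node_estimates[c] for c in sub.children],
            node_estimates[sub.factor],
            v, dv_corr=dv_corr)
        conditionals[sub.factor].append(parent_est)
        for child, est in zip(sub.children, child_ests):
            conditionals[child].append(est)

    out: list[EffectDecomposition] = []
    for node_id in tree.nodes:
        marg = node_estimates.get(node_id)
        ests = conditionals[node_id]
        if marg is None or not ests:
            out.append(EffectDecomposition(
                snp=snp, node=node_id,
                marginal_beta=marg[0] if marg else None,
                marginal_se=marg[1] if marg else None,
                conditional_beta=None, conditional_se=None,
                clogg_z=None, clogg_p=None, classification="na",
                provenance={"reason": "missing marginal" if marg is None
                            else "no conditional estimate"}))
            continue
        chosen, tie = select_min_z(ests)
        z, p = clogg_test(marg[0], marg[1], chosen.beta, chosen.se)
        classification = "direct_only" if p > alpha else "attenuated"
        prov = {"subtree": chosen.subtree, "role": chosen.role,
                "abs_z": abs(chosen.z), "tie": tie,
                "n_candidates": len(ests)}
        marg_z = marg[0] / marg[1]
        if abs(marg_z) < sps.norm.isf(alpha / 2):
            prov["null_marginal"] = True   # direct-only by vacuity
        out.append(EffectDecomposition(
            snp=snp, node=node_id,
            marginal_beta=marg[0], marginal_se=marg[1],
            conditional_beta=chosen.beta, conditional_se=chosen.se,
            clogg_z=z, clogg_p=p, classification=classification,
            provenance=prov))
    return out


def decomposition_table(decomps: Sequence[EffectDecomposition]) -> pd.DataFrame:
    rows = []
    for d in decomps:
        rows.append((d.snp, d.node, d.marginal_beta, d.marginal_se,
                     d.conditional_beta, d.conditional_se, d.clogg_z,
                     d.clogg_p, d.classification,
                     d.provenance.get("subtree"), d.provenance.get("role"),
                     bool(d.provenance.get("null_marginal", False))))
    return pd.DataFrame(rows, columns=[
        "snp", "node", "marginal_beta", "marginal_se", "conditional_beta",
        "conditional_se", "clogg_z", "clogg_p", "class", "subtree", "role",
        "null_marginal"])


def tree_overlay_json(
    tree: FactorTree,
    decomps: Sequence[EffectDecomposition],
    p_threshold: float | None = None,
    shrink_nonsignificant: bool = True,
) -> dict:
    """Per-SNP overlay of marginal/conditional effects on the tree, for
    path-graph displays.

    Returns a JSON-ready dict with one node entry per tree node (effects,
    classification, optional display-shrunk values) and the tree edges with
    their loadings.  Purely a plot-layer artefact.
    """
    by_node = {d.node: d for d in decomps}
    snp = decomps[0].snp if decomps else None
    nodes = {}
    for node_id, node in tree.nodes.items():
        d = by_node.get(node_id)
        entry: dict = {"label": node.label, "level": node.level}
        if d is not None:
            entry.update({
                "marginal_beta": d.marginal_beta,
                "conditional_beta": d.conditional_beta,
                "classification": d.classification,
            })
            if p_threshold is not None and d.clogg_p is not None:
                for key, beta, se in (
                        ("display_marginal", d.marginal_beta, d.marginal_se),
                        ("display_conditional", d.conditional_beta,
                         d.conditional_se)):
                    if beta is None:
                        continue
                    p = 2 * sps.norm.sf(abs(beta / se))
                    hide = (p >= p_threshold) if shrink_nonsignificant \
                        else (p < p_threshold)
                    entry[key] = 0.0 if hide else beta
        nodes[node_id] = entry
    edges = [{"parent": n.id, "child": c, "loading": n.loadings[c]}
             for n in tree.factors() for c in n.children]
    return {"snp": snp, "nodes": nodes, "edges": edges}


def shrink_for_display(
    table: pd.DataFrame,
    p_threshold: float,
    shrink_nonsignificant: bool = True,
) -> pd.DataFrame:
    """Plot-layer shrinkage of effect sizes for tree-overlay displays.

    Never used in inference.  By default effects with p >= threshold are
    shrunk to 0 (the conventional direction); the flag allows the inverted
    convention.  Returns a copy with ``display_beta`` columns added.
    """
    out = table.copy()
    for col, pcol in (("marginal_beta", "marginal_p"),
                      ("conditional_beta", "conditional_p")):
        if pcol not in out.columns:
            if col == "marginal_beta":
                z = out["marginal_beta"] / out["marginal_se"]
            else:
                z = out["conditional_beta"] / out["conditional_se"]
            out[pcol] = 2 * sps.norm.sf(np.abs(z))
        mask = (out[pcol] >= p_threshold) if shrink_nonsignificant \
            else (out[pcol] < p_threshold)
        out[f"display_{col}"] = np.where(mask, 0.0, out[col])
    return out
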