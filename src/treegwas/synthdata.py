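"""Synthetic cohorts and summary statistics with known ground truth.

The generator emulates the data-generating assumptions of the liking-GWAS
design: ``N`` unrelated individuals typed at ``M`` independent biallelic SNPs,
``T`` ordinal traits produced by a known multi-level factor tree.  Every node
of the tree has unit variance on the standardized scale: a non-root node is

    v_node = lambda * v_parent + g_node + u_node,

where ``g_node`` is the sum of planted SNP effects targeted at that node
(standardized genotypes times effect sizes), and ``u_node`` is a Gaussian
disturbance sized so the total variance is exactly 1.  Leaf traits optionally
pass through a 9-point hedonic-scale discretization (equal-probability
quantile thresholds, scored 1..9 from extreme dislike to extreme like).

Because the SNPs are independent and genotypes are standardized, the implied
marginal effect of a SNP planted at node ``n`` on leaf ``i`` is the planted
effect times the product of loadings on the path from ``n`` down to ``i`` —
recorded exactly in :class:`SimTruth` and used by every recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .geneprior import AnnotationBundle
from .sumstats import TraitSumStats

__all__ = [
    "TreeNodeSpec",
    "SimConfig",
    "SimTruth",
    "parse_tree_spec",
    "simulate_cohort",
    "simulate_sumstats",
    "discretize_likert",
    "implied_pheno_corr",
    "polygenic_effects",
    "make_annotation_fixture",
    "random_annotation_bundle",
    "variants_table",
]

_VAR_TOL = 1e-8


# ---------------------------------------------------------------------------
# tree specification
# ---------------------------------------------------------------------------

@dataclass
class TreeNodeSpec:
    """One node of the generative factor tree.

    ``loading`` is the standardized path coefficient linking this node to its
    parent (ignored for roots).  A node without children is a leaf trait.
    """

    id: str
    loading: float = 1.0
    children: list["TreeNodeSpec"] = field(default_factory=list)


def parse_tree_spec(spec: Any) -> list[TreeNodeSpec]:
    """Accept nested dicts / lists / TreeNodeSpec and return root specs."""
    if isinstance(spec, TreeNodeSpec):
        return [spec]
    if isinstance(spec, Mapping):
        children = [c for child in spec.get("children", [])
                    for c in parse_tree_spec(child)]
        return [TreeNodeSpec(str(spec["id"]), float(spec.get("loading", 1.0)),
                             children)]
    if isinstance(spec, Sequence) and not isinstance(spec, (str, bytes)):
        return [r for item in spec for r in parse_tree_spec(item)]
    raise TypeError(f"cannot interpret tree specification element: {spec!r}")


def _spec_to_dicts(roots: list[TreeNodeSpec]) -> list[dict]:
    def one(node: TreeNodeSpec) -> dict:
        d: dict = {"id": node.id, "loading": node.loading}
        if node.children:
            d["children"] = [one(c) for c in node.children]
        return d
    return [one(r) for r in roots]


class _Tree:
    """Flattened tree with parent pointers and path-product helpers."""

    def __init__(self, roots: list[TreeNodeSpec]):
        self.loading: dict[str, float] = {}
        self.parent: dict[str, str | None] = {}
        self.children: dict[str, list[str]] = {}
        self.order: list[str] = []          # topological, parents first
        for root in roots:
            self._add(root, None)
        self.roots = [r.id for r in roots]
        self.leaves = [n for n in self.order if not self.children[n]]

    def _add(self, node: TreeNodeSpec, parent: str | None) -> None:
        if node.id in self.loading:
            raise ValueError(f"duplicate node id in tree_spec: {node.id!r}")
        if not -1.0 <= node.loading <= 1.0:
            raise ValueError(
                f"loading for node {node.id!r} outside [-1, 1]: {node.loading}")
        self.loading[node.id] = float(node.loading)
        self.parent[node.id] = parent
        self.children[node.id] = [c.id for c in node.children]
        self.order.append(node.id)
        for child in node.children:
            self._add(child, node.id)

    def path_product(self, ancestor: str, leaf: str) -> float:
        """Product of loadings from ``ancestor`` down to ``leaf``.

        Returns 0.0 when ``ancestor`` is not on the leaf's ancestry path,
        and 1.0 when ``ancestor == leaf``.
        """
        prod, node = 1.0, leaf
        while node is not None:
            if node == ancestor:
                return prod
            prod *= self.loading[node]
            node = self.parent[node]
        return 0.0


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generative settings for one synthetic study."""

    n_individuals: int
    n_snps: int
    tree_spec: Any
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: list[tuple[int, str, float]] = field(default_factory=list)
    residual_variances: dict[str, float] | None = None
    likert_levels: int = DEFAULTS.likert_levels
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5: {self.maf_range}")
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        self._tree = _Tree(parse_tree_spec(self.tree_spec))
        for idx, node, beta in self.causal_snps:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index out of range: {idx}")
            if node not in self._tree.loading:
                raise ValueError(f"causal target {node!r} not in tree_spec")
            if abs(beta) > 1:
                raise ValueError(f"implausible standardized effect {beta} at {node!r}")

    @property
    def tree(self) -> _Tree:
        return self._tree

    @property
    def traits(self) -> list[str]:
        return self._tree.leaves

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        from pathlib import Path
        import yaml
        Path(path).write_text(yaml.safe_dump({
            "n_individuals": self.n_individuals,
            "n_snps": self.n_snps,
            "maf_range": list(self.maf_range),
            "tree_spec": _spec_to_dicts(parse_tree_spec(self.tree_spec)),
            "causal_snps": [[int(i), n, float(b)]
                            for i, n, b in self.causal_snps],
            "residual_variances": self.residual_variances,
            "likert_levels": self.likert_levels,
            "seed": self.seed,
        }, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        from pathlib import Path
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        data["maf_range"] = tuple(data["maf_range"])
        data["causal_snps"] = [(int(i), str(n), float(b))
                               for i, n, b in data.get("causal_snps", [])]
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth implied by a :class:`SimConfig`."""

    true_rg: pd.DataFrame          # trait x trait genetic correlations
    true_h2: pd.Series             # per-trait SNP heritability
    true_beta: pd.DataFrame        # SNP x trait marginal standardized effects
    node_assignments: dict[int, str]
    pheno_corr: pd.DataFrame       # implied phenotypic correlation (continuous scale)
    variants: pd.DataFrame         # snp, chrom, pos, ea, oa


def _node_effect_variance(config: SimConfig) -> dict[str, float]:
    var: dict[str, float] = {n: 0.0 for n in config.tree.order}
    for _, node, beta in config.causal_snps:
        var[node] += beta * beta
    return var


def _disturbance_variances(config: SimConfig) -> dict[str, float]:
    """Per-node variance of the Gaussian innovation keeping var(node)=1."""
    tree = config.tree
    effect_var = _node_effect_variance(config)
    out: dict[str, float] = {}
    for node in tree.order:
        lam = 0.0 if tree.parent[node] is None else tree.loading[node]
        implied = lam * lam + effect_var[node]
        if node in tree.leaves and config.residual_variances is not None:
            if node not in config.residual_variances:
                raise ValueError(f"residual_variances missing leaf {node!r}")
            resid = float(config.residual_variances[node])
            if abs(implied + resid - 1.0) > _VAR_TOL:
                raise ValueError(
                    f"configuration error: leaf {node!r} implied variance "
                    f"{implied + resid:.10f} != 1 (path+effects {implied:.10f}, "
                    f"residual {resid:.10f})")
            out[node] = resid
            continue
        resid = 1.0 - implied
        if resid < -_VAR_TOL:
            raise ValueError(
                f"configuration error: node {node!r} implied variance {implied:.6f} "
                "exceeds 1 (negative residual)")
        out[node] = max(resid, 0.0)
    return out


def _true_beta(config: SimConfig) -> pd.DataFrame:
    traits = config.traits
    beta = np.zeros((config.n_snps, len(traits)))
    for idx, node, b in config.causal_snps:
        for t, leaf in enumerate(traits):
            beta[idx, t] += b * config.tree.path_product(node, leaf)
    snps = variants_table(config.n_snps)["snp"]
    return pd.DataFrame(beta, index=snps, columns=traits)


def sim_truth(config: SimConfig) -> SimTruth:
    """Exact truth tables implied by the configuration (no simulation)."""
    traits = config.traits
    beta = _true_beta(config)
    gcov = beta.to_numpy().T @ beta.to_numpy()
    h2 = np.diag(gcov).copy()
    denom = np.sqrt(np.outer(h2, h2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = np.where(denom > 0, gcov / denom, 0.0)
    np.fill_diagonal(rg, 1.0)
    return SimTruth(
        true_rg=pd.DataFrame(rg, index=traits, columns=traits),
        true_h2=pd.Series(h2, index=traits, name="h2"),
        true_beta=beta,
        node_assignments={idx: node for idx, node, _ in config.causal_snps},
        pheno_corr=implied_pheno_corr(config),
        variants=variants_table(config.n_snps),
    )


def implied_pheno_corr(config: SimConfig) -> pd.DataFrame:
    """Phenotypic correlation among leaf traits implied by the tree model.

    Computed analytically from shared SNP effects and shared node
    disturbances (leaf residuals only contribute to the diagonal, which is 1
    by the unit-variance bookkeeping).
    """
    tree = config.tree
    traits = tree.leaves
    disturb = _disturbance_variances(config)
    beta = _true_beta(config).to_numpy()
    cov = beta.T @ beta
    for node in tree.order:
        paths = np.array([tree.path_product(node, leaf) for leaf in traits])
        cov += disturb[node] * np.outer(paths, paths)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=traits, columns=traits)


# ---------------------------------------------------------------------------
# variant bookkeeping
# ---------------------------------------------------------------------------

def variants_table(n_snps: int, spacing: int = 10_000, n_chrom: int = 22) -> pd.DataFrame:
    """Deterministic variant metadata: ids, chromosome blocks, positions."""
    per = math.ceil(n_snps / n_chrom)
    chrom = [str(1 + i // per) for i in range(n_snps)]
    pos = [1_000_000 + (i % per) * spacing for i in range(n_snps)]
    return pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n_snps)],
        "chrom": chrom,
        "pos": pos,
        "ea": "A",
        "oa": "G",
    })


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame, SimTruth]:
    """Draw genotypes and tree-structured phenotypes for one cohort.

    Returns ``(dosages, phenotypes, truth)`` where ``dosages`` is an
    ``(N, M)`` array of 0/1/2 counts, ``phenotypes`` has one column per leaf
    trait (discretized to ``likert_levels`` when that is >= 2), and ``truth``
    carries the implied marginal effects, heritabilities and correlations.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    n, m = config.n_individuals, config.n_snps

    freqs = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    # standardize with the true allele frequency so planted effects are exact
    x = (dosages - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))

    effects: dict[str, np.ndarray] = {node: np.zeros(n) for node in tree.order}
    for idx, node, beta in config.causal_snps:
        effects[node] = effects[node] + beta * x[:, idx]

    disturb = _disturbance_variances(config)
    values: dict[str, np.ndarray] = {}
    for node in tree.order:
        parent = tree.parent[node]
        base = np.zeros(n) if parent is None else tree.loading[node] * values[parent]
        noise = rng.normal(0.0, np.sqrt(disturb[node]), size=n)
        values[node] = base + effects[node] + noise

    pheno = pd.DataFrame({leaf: values[leaf] for leaf in tree.leaves})
    if config.likert_levels >= 2:
        pheno = pheno.apply(lambda col: discretize_likert(col.to_numpy(),
                                                          config.likert_levels))
    return dosages, pheno, sim_truth(config)


def simulate_sumstats(
    config: SimConfig,
    pheno_corr: pd.DataFrame | np.ndarray | None = None,
) -> tuple[dict[str, TraitSumStats], SimTruth]:
    """Draw per-trait summary statistics directly (the fast path).

    For each SNP the vector of estimates across traits is multivariate
    normal with mean equal to the true marginal effects and sampling
    covariance ``pheno_corr / N`` — the full-sample-overlap model of a single
    cohort analysed for all traits.  Standard errors are the exact
    standardized-scale ``1/sqrt(N)``.  Independent cohorts are simulated by
    separate calls with distinct seeds.
    """
    truth = sim_truth(config)
    traits = config.traits
    if pheno_corr is None:
        corr = truth.pheno_corr.to_numpy()
    elif isinstance(pheno_corr, pd.DataFrame):
        corr = pheno_corr.loc[traits, traits].to_numpy()
    else:
        corr = np.asarray(pheno_corr, float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pheno_corr is not positive definite") from exc

    rng = np.random.default_rng(config.seed)
    n_ind, m = config.n_individuals, config.n_snps
    noise = rng.standard_normal((m, len(traits))) @ chol.T / np.sqrt(n_ind)
    beta_hat = truth.true_beta.to_numpy() + noise
    se = 1.0 / np.sqrt(n_ind)

    from scipy import stats as sps
    variants = truth.variants
    out: dict[str, TraitSumStats] = {}
    for t, trait in enumerate(traits):
        z = beta_hat[:, t] / se
        p = 2.0 * sps.norm.sf(np.abs(z))
        tab = variants.copy()
        tab["eaf"] = 0.5  # standardized scale: frequency is bookkeeping only
        tab["beta"] = beta_hat[:, t]
        tab["se"] = se
        tab["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
        tab["n"] = n_ind
        out[trait] = TraitSumStats(trait, tab)
    return out, truth


def discretize_likert(values: np.ndarray, levels: int = DEFAULTS.likert_levels) -> np.ndarray:
    """Bin a continuous trait into 1..levels by equal-probability thresholds."""
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    values = np.asarray(values, float)
    if np.ptp(values) == 0:
        raise ValueError("constant input: quantile thresholds are undefined")
    qs = np.quantile(values, np.arange(1, levels) / levels)
    return (1 + np.searchsorted(qs, values, side="left")).astype(int)


def polygenic_effects(
    rng: np.random.Generator,
    node_variance: Mapping[str, float],
    n_per_node: int,
    n_snps: int,
) -> list[tuple[int, str, float]]:
    """Spread each node's genetic variance over ``n_per_node`` random SNPs.

    Effects are ``+/- sqrt(var / n_per_node)`` with random signs; SNP indices
    are drawn without replacement across nodes so targets never collide.
    """
    need = n_per_node * len(node_variance)
    if need > n_snps:
        raise ValueError(f"need {need} causal SNPs but only {n_snps} available")
    idx = rng.choice(n_snps, size=need, replace=False)
    out: list[tuple[int, str, float]] = []
    for k, (node, var) in enumerate(node_variance.items()):
        b = math.sqrt(var / n_per_node)
        for j in idx[k * n_per_node:(k + 1) * n_per_node]:
            out.append((int(j), node, b * (1 if rng.random() < 0.5 else -1)))
    return out


# ---------------------------------------------------------------------------
# annotation fixtures for gene prioritization
# ---------------------------------------------------------------------------

def make_annotation_fixture(
    seed: int,
    n_genes: int = 10,
    n_snps: int | None = None,
    sentinels: Sequence[str] | None = None,
) -> tuple[AnnotationBundle, pd.DataFrame]:
    """Internally consistent toy annotation set with a known intended answer.

    One sentinel is planted per gene, cycling through the five prioritization
    rules; the returned table records, for each sentinel, the gene and rule
    the prioritizer is expected to report.  Synthetic stand-in for external
    LD / consequence resources; fully offline and deterministic under seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    gene_len, gap = 20_000, 60_000
    genes = pd.DataFrame({
        "gene": [f"GENE{i + 1}" for i in range(n_genes)],
        "chrom": "1",
        "start": [100_000 + i * (gene_len + gap) for i in range(n_genes)],
        "end": [100_000 + i * (gene_len + gap) + gene_len - 1 for i in range(n_genes)],
    })
    if sentinels is None:
        sentinels = [f"sent{i + 1}" for i in range(n_genes)]
    elif len(sentinels) != n_genes:
        raise ValueError("need exactly one sentinel per gene")

    ld_rows, csq_rows, pos_rows, expected = [], [], [], []
    for i, sent in enumerate(sentinels):
        gene = genes.iloc[i]
        rule = (i % 5) + 1
        inside = int(gene.start + 5_000 + rng.integers(0, 5_000))
        if rule == 5:
            # intergenic, no LD partners, no consequences: closest gene wins
            pos_rows.append((sent, "1", int(gene.start - 10_000)))
        else:
            pos_rows.append((sent, "1", inside))
        proxy = f"{sent}_prox"
        if rule == 1:
            ld_rows.append((sent, proxy, 0.9))
            csq_rows.append((proxy, gene.gene, "nonsynonymous"))
            pos_rows.append((proxy, "1", inside + 100))
        elif rule == 2:
            ld_rows.append((sent, proxy, 0.9))
            csq_rows.append((proxy, gene.gene, "utr3"))
            pos_rows.append((proxy, "1", inside + 100))
        elif rule == 3:
            csq_rows.append((sent, gene.gene, "intronic"))
        elif rule == 4:
            ld_rows.append((sent, proxy, 0.85))
            csq_rows.append((proxy, gene.gene, "intronic"))
            pos_rows.append((proxy, "1", inside + 100))
        expected.append((sent, gene.gene, rule))

    if n_snps is not None:
        have = len(pos_rows)
        for j in range(max(0, n_snps - have)):
            pos_rows.append((f"null{j + 1}", "1",
                             int(rng.integers(50_000, genes.end.max() + 50_000))))

    bundle = AnnotationBundle(
        ld=pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"]),
        consequences=pd.DataFrame(csq_rows, columns=["snp", "gene", "class"]),
        genes=genes,
        snp_pos=pd.DataFrame(pos_rows, columns=["snp", "chrom", "pos"]),
    )
    return bundle, pd.DataFrame(expected, columns=["sentinel", "gene", "rule"])


_CSQ_CLASSES = ("nonsynonymous", "synonymous", "utr3", "utr5", "intronic", "intergenic")


def random_annotation_bundle(
    rng: np.random.Generator,
    n_genes: int = 6,
    n_snps: int = 12,
) -> tuple[AnnotationBundle, str]:
    """Random but internally consistent bundle plus a sentinel id.

    Used by property tests that compare the prioritizer against a brute-force
    rule evaluator; makes no promise about which rule fires.
    """
    genes = pd.DataFrame({
        "gene": [f"G{i + 1}" for i in range(n_genes)],
        "chrom": "1",
        "start": sorted(rng.choice(np.arange(10, 2_000) * 1_000, n_genes, replace=False)),
    })
    genes["end"] = genes["start"] + int(rng.integers(5_000, 40_000))
    snps = [f"s{i + 1}" for i in range(n_snps)]
    pos = pd.DataFrame({
        "snp": snps,
        "chrom": "1",
        "pos": rng.integers(1_000, genes.end.max() + 100_000, n_snps),
    })
    sentinel = snps[0]
    ld_rows = []
    for other in snps[1:]:
        if rng.random() < 0.5:
            r2 = float(rng.choice([0.2, 0.5, 0.8, 0.85, 0.95, 1.0]))
            ld_rows.append((sentinel, other, r2))
    csq_rows = []
    for s in snps:
        if rng.random() < 0.6:
            csq_rows.append((s, f"G{int(rng.integers(1, n_genes + 1))}",
                             str(rng.choice(_CSQ_CLASSES))))
    bundle = AnnotationBundle(
        ld=pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"]),
        consequences=pd.DataFrame(csq_rows, columns=["snp", "gene", "class"]),
        genes=genes,
        snp_pos=pos,
    )
    return bundle, sentinel
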