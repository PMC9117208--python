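"""Cross-cohort harmonization, meta-analysis and replication testing.

Cohorts rate liking on different ordinal scales, so estimates are first
rescaled to a common 0-1 response scale by dividing beta and SE by the
scale range (p-values and z-scores are invariant).  Pre-meta QC is reduced
to allele harmonization (flip to the discovery effect allele), positive
SEs, valid p-values and available N.  Pooling is fixed-effects inverse
variance weighting; Cochran's Q is reported but not used for filtering.
An association replicates when the replication estimate has the discovery
direction and one-tailed p < 0.05; overall directional agreement is tested
with an exact binomial test against chance (p = 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULTS
from .sumstats import TraitSumStats

__all__ = [
    "CohortResult",
    "MetaResult",
    "rescale_to_unit",
    "harmonize_alleles",
    "ivw_meta",
    "test_replication",
    "sign_consistency_test",
    "filter_testable",
    "replication_report",
]


@dataclass
class CohortResult:
    """One cohort's summary statistics with its response-scale bounds."""

    cohort: str
    stats: TraitSumStats
    scale_min: float
    scale_max: float
    n: int

    def __post_init__(self) -> None:
        if self.scale_max <= self.scale_min:
            raise ValueError(
                f"cohort {self.cohort!r}: scale_max must exceed scale_min")
        if self.n <= 0:
            raise ValueError(f"cohort {self.cohort!r}: n must be positive")


def rescale_to_unit(stats: TraitSumStats, scale_min: float,
                    scale_max: float) -> TraitSumStats:
    """Rescale beta and SE to a 0-1 response scale (divide by the range)."""
    rng = scale_max - scale_min
    if rng <= 0:
        raise ValueError("zero or negative scale range")
    tab = stats.table.copy()
    tab["beta"] = tab["beta"] / rng
    tab["se"] = tab["se"] / rng
    return TraitSumStats(stats.trait, tab, dict(stats.provenance))


def harmonize_alleles(discovery: TraitSumStats,
                      other: TraitSumStats) -> TraitSumStats:
    """Flip ``other`` to the discovery effect allele; drop mismatches.

    Rows whose allele pair does not match the discovery pair in either
    orientation are removed.  Basic QC (positive SE, valid p, available N)
    is enforced by the TraitSumStats invariants on construction.
    """
    disc = discovery.indexed()
    tab = other.indexed()
    common = disc.index.intersection(tab.index)
    tab = tab.loc[common].copy()
    ref = disc.loc[common]
    same = (tab["ea"] == ref["ea"]) & (tab["oa"] == ref["oa"])
    flipped = (tab["ea"] == ref["oa"]) & (tab["oa"] == ref["ea"])
    tab.loc[flipped, "beta"] = -tab.loc[flipped, "beta"]
    tab.loc[flipped, "eaf"] = 1.0 - tab.loc[flipped, "eaf"]
    tab.loc[flipped, ["ea", "oa"]] = ref.loc[flipped, ["ea", "oa"]].to_numpy()
    keep = same | flipped
    return TraitSumStats(other.trait, tab.loc[keep].reset_index(drop=True),
                         dict(other.provenance))


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    q: float
    q_df: int
    q_p: float
    n_studies: int


def ivw_meta(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Fixed-effects inverse-variance-weighted pooling.

    ``estimates`` is a list of (beta, se); Cochran's Q heterogeneity is
    reported alongside.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to meta-analyse")
    betas = np.array([b for b, _ in estimates], float)
    ses = np.array([s for _, s in estimates], float)
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * sps.norm.sf(abs(beta / se)))
    q = float(np.sum(w * (betas - beta) ** 2))
    q_df = len(betas) - 1
    q_p = float(sps.chi2.sf(q, q_df)) if q_df > 0 else 1.0
    return MetaResult(beta, se, p, q, q_df, q_p, len(betas))


def test_replication(
    discovery_beta: float,
    replication_beta: float,
    replication_se: float,
    alpha: float = DEFAULTS.replication_alpha,
) -> tuple[bool, float, bool]:
    """One-tailed replication test in the discovery direction.

    Returns (replicated, one-tailed p, sign-consistent): replicated means
    same direction AND one-tailed p < alpha.
    """
    if discovery_beta == 0:
        raise ValueError("discovery effect is zero: direction undefined")
    if replication_se <= 0:
        raise ValueError("replication SE must be positive")
    z_dir = np.sign(discovery_beta) * replication_beta / replication_se
    p_one = float(sps.norm.sf(z_dir))
    sign_ok = bool(z_dir > 0)
    return bool(sign_ok and p_one < alpha), p_one, sign_ok


def sign_consistency_test(k_consistent: int, n_total: int) -> float:
    """Exact one-tailed binomial tail P(X >= k | n, 1/2)."""
    if n_total == 0:
        raise ValueError("no associations to test")
    if not 0 <= k_consistent <= n_total:
        raise ValueError("k_consistent must lie in [0, n_total]")
    return float(sps.binomtest(k_consistent, n_total, 0.5,
                               alternative="greater").pvalue)


def filter_testable(
    combined_n: Mapping[str, float],
    min_n: int = DEFAULTS.min_n,
) -> tuple[list[str], pd.DataFrame]:
    """Traits with combined replication N of at least ``min_n``.

    Returns (kept trait ids, audit table of all traits with the decision).
    """
    rows = [(t, n, n >= min_n) for t, n in combined_n.items()]
    audit = pd.DataFrame(rows, columns=["trait", "combined_n", "testable"])
    return audit.loc[audit["testable"], "trait"].tolist(), audit


def load_cohorts(manifest_path) -> list[CohortResult]:
    """Read a cohort manifest YAML: a list of entries with keys
    cohort, file (summary-statistics TSV, path relative to the manifest),
    scale_min, scale_max, n."""
    import yaml
    from pathlib import Path
    from .io import read_sumstats
    path = Path(manifest_path)
    entries = yaml.safe_load(path.read_text()) or []
    out = []
    for e in entries:
        stats = read_sumstats(path.parent / e["file"])
        out.append(CohortResult(cohort=str(e["cohort"]), stats=stats,
                                scale_min=float(e["scale_min"]),
                                scale_max=float(e["scale_max"]),
                                n=int(e["n"])))
    return out


def replication_report(
    discovery: pd.DataFrame,
    cohorts: Iterable[CohortResult],
    min_n: int = DEFAULTS.min_n,
    alpha: float = DEFAULTS.replication_alpha,
) -> pd.DataFrame:
    """Meta-analyse replication cohorts and test each discovery association.

    ``discovery`` needs columns (trait, snp, beta, p).  Cohort statistics
    are rescaled to the unit response scale, harmonized per trait, pooled
    with IVW, and each (trait, snp) association is tested one-tailed in the
    discovery direction.  Associations are testable when the combined
    cohort N for the trait reaches ``min_n`` and the SNP is present in the
    meta-analysis.
    """
    by_trait: dict[str, list[CohortResult]] = {}
    for c in cohorts:
        by_trait.setdefault(c.stats.trait, []).append(c)
    combined = {t: sum(c.n for c in cs) for t, cs in by_trait.items()}
    testable_traits, _ = filter_testable(combined, min_n=min_n)

    rows = []
    for _, assoc in discovery.iterrows():
        trait, snp = assoc["trait"], assoc["snp"]
        entry = {
            "trait": trait, "snp": snp,
            "discovery_beta": assoc["beta"], "discovery_p": assoc["p"],
            "testable": False, "meta_beta": np.nan, "meta_se": np.nan,
            "meta_p": np.nan, "one_tailed_p": np.nan,
            "replicated": False, "sign_consistent": False,
        }
        if trait in testable_traits:
            ests = []
            for c in by_trait[trait]:
                scaled = rescale_to_unit(c.stats, c.scale_min, c.scale_max)
                hit = scaled.indexed()
                if snp in hit.index:
                    ests.append((float(hit.loc[snp, "beta"]),
                                 float(hit.loc[snp, "se"])))
            if ests:
                meta = ivw_meta(ests)
                rep, p_one, sign_ok = test_replication(
                    float(assoc["beta"]), meta.beta, meta.se, alpha=alpha)
                entry.update(testable=True, meta_beta=meta.beta,
                             meta_se=meta.se, meta_p=meta.p,
                             one_tailed_p=p_one, replicated=rep,
                             sign_consistent=sign_ok)
        rows.append(entry)
    return pd.DataFrame(rows)
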