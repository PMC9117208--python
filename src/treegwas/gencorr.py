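"""SNP heritability, genetic correlations and the study-wide threshold.

With independent SNPs (the synthetic design used throughout), LD scores are
constant and LD-score regression degenerates to its moment special case,
which is what this module implements:

    h2_hat = M * (mean(chi2) - a) / N            (a = 1 with no confounding)
    gcov   = M * (mean(z_a z_b) - rho_s) / sqrt(N_a N_b)
    rg     = gcov / sqrt(h2_a h2_b)

``rho_s`` is the expected null cross-trait z-product, N_s * rho_P /
sqrt(N_a N_b); under full sample overlap of one cohort it equals the
phenotypic correlation.  Standard errors come from a delete-one block
jackknife over contiguous SNP blocks (200 blocks by default).

The effective number of independent tests is the smallest count of
eigen-components of the rg matrix reaching a target variance share; the
study-wide significance threshold is the genome-wide alpha divided by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULTS
from .sumstats import TraitSumStats, align_snps

__all__ = [
    "GeneticCorrMatrix",
    "MultiplicityResult",
    "UndefinedCorrelationError",
    "estimate_h2",
    "estimate_rg",
    "estimate_sampling_offset",
    "build_corr_matrix",
    "compare_h2",
    "effective_components",
]

log = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """A genetic correlation with a non-positive heritability component."""

    def __init__(self, msg: str, h2_a: float, h2_b: float):
        super().__init__(msg)
        self.h2_a = h2_a
        self.h2_b = h2_b


def _blocks(m: int, n_blocks: int) -> list[np.ndarray]:
    if m < n_blocks:
        raise ValueError(f"fewer SNPs ({m}) than jackknife blocks ({n_blocks})")
    return np.array_split(np.arange(m), n_blocks)


def _jackknife_se(loo: np.ndarray) -> float:
    """SE from leave-one-block-out estimates."""
    b = len(loo)
    return float(np.sqrt((b - 1) / b * np.sum((loo - loo.mean()) ** 2)))


def estimate_h2(
    stats: TraitSumStats,
    m_snps: int | None = None,
    n_blocks: int = DEFAULTS.jackknife_blocks,
    intercept: float = DEFAULTS.h2_intercept,
) -> tuple[float, float]:
    """Moment estimate of SNP heritability with a block-jackknife SE.

    ``m_snps`` defaults to the number of rows; the scan must carry per-SNP
    sample sizes (standardized scale assumed).
    """
    if "n" not in stats.table.columns or stats.table["n"].isna().any():
        raise ValueError(f"sample size N missing for trait {stats.trait!r}")
    chi2 = stats.z() ** 2
    m = int(m_snps) if m_snps is not None else len(chi2)
    n = stats.mean_n
    blocks = _blocks(len(chi2), n_blocks)
    h2 = m * (chi2.mean() - intercept) / n
    total = chi2.sum()
    loo = np.array([
        m * ((total - chi2[b].sum()) / (len(chi2) - len(b)) - intercept) / n
        for b in blocks
    ])
    return float(h2), _jackknife_se(loo)


def estimate_sampling_offset(a: TraitSumStats, b: TraitSumStats,
                             decile: float = 0.1) -> float:
    """Heuristic rho_s: mean cross-trait z-product over SNPs in the bottom
    ``decile`` of both traits' chi-square (effectively null SNPs).

    Unidentifiable exactly without LD variation; prefer supplying rho_s from
    the study design when it is known.
    """
    aa, bb = align_snps([a, b])
    za, zb = aa.z(), bb.z()
    qa = np.quantile(za ** 2, decile)
    qb = np.quantile(zb ** 2, decile)
    mask = (za ** 2 <= qa) & (zb ** 2 <= qb)
    if mask.sum() < 10:
        raise ValueError("too few null SNPs to estimate the sampling offset")
    return float((za[mask] * zb[mask]).mean())


def estimate_rg(
    a: TraitSumStats,
    b: TraitSumStats,
    rho_s: float = 0.0,
    n_blocks: int = DEFAULTS.jackknife_blocks,
    intercept: float = DEFAULTS.h2_intercept,
) -> tuple[float, float]:
    """Genetic correlation between two traits with a jackknife SE.

    ``rho_s`` is the expected null z-product from sample overlap (the
    phenotypic correlation under full overlap, 0 for disjoint cohorts).
    """
    aa, bb = align_snps([a, b])
    za, zb = aa.z(), bb.z()
    m = len(za)
    na, nb = aa.mean_n, bb.mean_n
    sqrt_n = np.sqrt(na * nb)

    prod = za * zb
    chia, chib = za ** 2, zb ** 2
    h2a = m * (chia.mean() - intercept) / na
    h2b = m * (chib.mean() - intercept) / nb
    if h2a <= 0 or h2b <= 0:
        raise UndefinedCorrelationError(
            f"undefined genetic correlation between {a.trait!r} and {b.trait!r}: "
            f"h2 estimates {h2a:.4g}, {h2b:.4g}", h2a, h2b)
    gcov = m * (prod.mean() - rho_s) / sqrt_n
    rg = gcov / np.sqrt(h2a * h2b)

    blocks = _blocks(m, n_blocks)
    t_prod, t_a, t_b = prod.sum(), chia.sum(), chib.sum()
    loo = np.empty(len(blocks))
    for i, blk in enumerate(blocks):
        rest = m - len(blk)
        mp = (t_prod - prod[blk].sum()) / rest
        ha = m * ((t_a - chia[blk].sum()) / rest - intercept) / na
        hb = m * ((t_b - chib[blk].sum()) / rest - intercept) / nb
        denom = np.sqrt(max(ha, 1e-12) * max(hb, 1e-12))
        loo[i] = m * (mp - rho_s) / sqrt_n / denom
    return float(rg), _jackknife_se(loo)


@dataclass
class GeneticCorrMatrix:
    """Pairwise genetic correlations plus per-trait heritabilities."""

    traits: list[str]
    rg: pd.DataFrame
    rg_se: pd.DataFrame
    h2: pd.Series
    h2_se: pd.Series
    rho_s: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        return self.rg.loc[self.traits, self.traits].to_numpy()

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, ta in enumerate(self.traits):
            for tb in self.traits[i + 1:]:
                r, se = self.rg.loc[ta, tb], self.rg_se.loc[ta, tb]
                z = r / se if se > 0 else np.inf
                rows.append((ta, tb, r, se, 2 * sps.norm.sf(abs(z))))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "rg", "se", "p"])

    def write(self, prefix) -> None:
        """Square CSVs (rg, rg_se, h2 row) and a long-format TSV."""
        from pathlib import Path
        prefix = Path(prefix)
        self.rg.to_csv(prefix.with_suffix(".rg.csv"))
        self.rg_se.to_csv(prefix.with_suffix(".rg_se.csv"))
        pd.DataFrame({"h2": self.h2, "h2_se": self.h2_se}).T.to_csv(
            prefix.with_suffix(".h2.csv"))
        self.to_long().to_csv(prefix.with_suffix(".rg.tsv"), sep="\t", index=False)


def build_corr_matrix(
    stats: dict[str, TraitSumStats],
    rho_s: pd.DataFrame | float = 0.0,
    n_blocks: int = DEFAULTS.jackknife_blocks,
    clamp: bool = True,
    psd_project: bool = False,
) -> GeneticCorrMatrix:
    """Assemble the full genetic correlation matrix over a set of traits.

    Traits whose heritability estimate is non-positive are excluded with a
    warning and recorded in ``flags['excluded']``.  |rg| > 1 estimates are
    clamped to +/-1 when ``clamp`` (recorded in ``flags['clamped']``); an
    optional nearest-PSD projection clips negative eigenvalues.
    """
    aligned = dict(zip(stats.keys(), align_snps(stats.values())))
    h2: dict[str, float] = {}
    h2_se: dict[str, float] = {}
    excluded: list[str] = []
    for trait, s in aligned.items():
        est, se = estimate_h2(s, n_blocks=n_blocks)
        if est <= 0:
            log.warning("excluding trait %r: h2 estimate %.4g <= 0", trait, est)
            excluded.append(trait)
        else:
            h2[trait], h2_se[trait] = est, se
    traits = list(h2)

    def offset(ta: str, tb: str) -> float:
        if isinstance(rho_s, pd.DataFrame):
            return float(rho_s.loc[ta, tb])
        return float(rho_s)

    k = len(traits)
    rg = np.eye(k)
    rg_se = np.zeros((k, k))
    rho = np.eye(k)
    clamped: list[tuple[str, str, float]] = []
    for i, ta in enumerate(traits):
        for j in range(i + 1, k):
            tb = traits[j]
            r, se = estimate_rg(aligned[ta], aligned[tb], rho_s=offset(ta, tb),
                                n_blocks=n_blocks)
            if clamp and abs(r) > 1:
                clamped.append((ta, tb, r))
                r = float(np.sign(r))
            rg[i, j] = rg[j, i] = r
            rg_se[i, j] = rg_se[j, i] = se
            rho[i, j] = rho[j, i] = offset(ta, tb)

    flags: dict = {"excluded": excluded, "clamped": clamped, "psd_projected": False}
    if psd_project:
        vals, vecs = np.linalg.eigh(rg)
        if vals.min() < 0:
            rg = vecs @ np.diag(np.clip(vals, 0, None)) @ vecs.T
            d = np.sqrt(np.diag(rg))
            rg = rg / np.outer(d, d)
            np.fill_diagonal(rg, 1.0)
            flags["psd_projected"] = True

    idx = pd.Index(traits)
    return GeneticCorrMatrix(
        traits=traits,
        rg=pd.DataFrame(rg, index=idx, columns=idx),
        rg_se=pd.DataFrame(rg_se, index=idx, columns=idx),
        h2=pd.Series(h2, name="h2"),
        h2_se=pd.Series(h2_se, name="h2_se"),
        rho_s=pd.DataFrame(rho, index=idx, columns=idx),
        flags=flags,
    )


def compare_h2(
    h2_a: float, se_a: float, h2_b: float, se_b: float,
    n_comparisons: int = 1,
    alpha: float = DEFAULTS.bonferroni_alpha,
) -> tuple[float, float, bool]:
    """Z-test for a heritability difference with Bonferroni correction."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (h2_a - h2_b) / np.sqrt(se_a ** 2 + se_b ** 2)
    p = float(2 * sps.norm.sf(abs(z)))
    return float(z), p, p < alpha / n_comparisons


@dataclass
class MultiplicityResult:
    """Effective number of tests from the rg-matrix eigen spectrum."""

    eigenvalues: np.ndarray
    n_components: int
    variance_share: float
    genomewide_alpha: float
    studywide_threshold: float


def effective_components(
    corr: GeneticCorrMatrix | pd.DataFrame | np.ndarray,
    share: float = DEFAULTS.variance_share,
    alpha: float = DEFAULTS.genomewide_alpha,
) -> MultiplicityResult:
    """Smallest number of eigen-components reaching ``share`` of variance.

    Negative eigenvalues (noisy, non-PSD rg matrices) are clipped to zero
    before cumulative shares are computed; the smallest k whose cumulative
    share is >= ``share`` wins (a 20x20 identity at 0.95 gives 19).
    """
    if isinstance(corr, GeneticCorrMatrix):
        mat = corr.matrix()
    elif isinstance(corr, pd.DataFrame):
        mat = corr.to_numpy(dtype=float)
    else:
        mat = np.asarray(corr, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not 0 < share <= 1:
        raise ValueError(f"share must be in (0, 1]: {share}")
    vals = np.sort(np.linalg.eigvalsh(mat))[::-1]
    clipped = np.clip(vals, 0.0, None)
    cum = np.cumsum(clipped) / clipped.sum()
    n = int(np.searchsorted(cum, share - 1e-12) + 1)
    return MultiplicityResult(
        eigenvalues=vals,
        n_components=n,
        variance_share=float(cum[n - 1]),
        genomewide_alpha=alpha,
        studywide_threshold=alpha / n,
    )
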