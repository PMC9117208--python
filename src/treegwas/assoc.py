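"""Per-trait GWAS on individual-level data.

Two-stage design: the trait is first residualized on covariates (age, sex,
principal components, ... — whatever columns are supplied), then each SNP is
tested with a simple additive linear regression of the residuals on dosage.
Cohorts are assumed unrelated, so no mixed-model correction is applied; no
samples are excluded by trait value.  P-values come from the t distribution
with n - 2 degrees of freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULTS
from .sumstats import TraitSumStats

__all__ = ["residualize", "run_trait_gwas"]

log = logging.getLogger(__name__)


def residualize(trait: np.ndarray, covariates: np.ndarray | pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of ``trait`` on an intercept plus ``covariates``.

    Residuals are orthogonal to every covariate column.  Raises on
    rank-deficient covariates, naming the collinear columns.
    """
    y = np.asarray(trait, float)
    if covariates is None:
        return y - y.mean()
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.atleast_2d(np.asarray(covariates, float))
        if c.shape[0] != y.shape[0] and c.shape[1] == y.shape[0]:
            c = c.T
        names = [f"cov{j}" for j in range(c.shape[1])]
    if c.shape[0] != y.shape[0]:
        raise ValueError("trait and covariates have different numbers of rows")

    x = np.column_stack([np.ones(len(y)), c])
    # rank check with named culprits via QR pivoting on the R diagonal
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    if (diag < tol).any():
        collinear = [(["intercept"] + names)[j] for j in np.where(diag < tol)[0]]
        raise ValueError(f"rank-deficient covariates; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def run_trait_gwas(
    dosages: np.ndarray,
    residuals: np.ndarray,
    maf_min: float = DEFAULTS.maf_min,
    trait: str = "trait",
    variants: pd.DataFrame | None = None,
) -> TraitSumStats:
    """Additive per-SNP regression of residualized trait on dosage.

    ``dosages`` is (N, M) with entries in [0, 2].  SNPs with minor-allele
    frequency not strictly above ``maf_min`` are excluded; zero-variance
    SNPs are skipped with a warning.  ``variants`` optionally supplies SNP
    metadata (snp, chrom, pos, ea, oa) aligned with the dosage columns.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5): {maf_min}")
    g = np.asarray(dosages, float)
    y = np.asarray(residuals, float)
    n, m = g.shape
    if len(y) != n:
        raise ValueError("residuals and dosage rows are not aligned")
    if y.std() == 0:
        raise ValueError("zero-variance residuals: nothing to regress")

    if variants is None:
        from .synthdata import variants_table
        variants = variants_table(m)
    elif len(variants) != m:
        raise ValueError("variants table does not match dosage columns")

    eaf = g.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    xc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)

    zero_var = sxx == 0
    if zero_var.any():
        log.warning("skipping %d zero-variance SNPs (e.g. %s)",
                    int(zero_var.sum()),
                    variants.loc[np.where(zero_var)[0][:3], "snp"].tolist())
    keep = (maf > maf_min) & ~zero_var

    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        syy = float((yc ** 2).sum())
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        # exact planted fits give rss = 0; keep se positive so z is finite
        se = np.maximum(np.sqrt(sigma2 / sxx), 1e-300)
        tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)

    tab = variants.loc[keep, ["snp", "chrom", "pos", "ea", "oa"]].copy()
    tab["eaf"] = eaf[keep]
    tab["beta"] = beta[keep]
    tab["se"] = se[keep]
    tab["p"] = np.clip(p[keep], np.nextafter(0, 1), 1.0)
    tab["n"] = n
    return TraitSumStats(trait, tab.reset_index(drop=True))
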