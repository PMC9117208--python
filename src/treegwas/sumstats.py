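"""The universal exchange format between pipeline stages.

A :class:`TraitSumStats` is one trait's per-SNP association results: a pandas
table with one row per SNP carrying effect sizes on the standardized scale
(unit-variance genotype and phenotype) unless noted otherwise, plus the trait
identifier.  Every stage of the pipeline consumes and produces this shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

__all__ = ["TraitSumStats", "REQUIRED_COLUMNS", "align_snps"]

#: Mandatory columns, in canonical order.
REQUIRED_COLUMNS = (
    "snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n",
)


@dataclass
class TraitSumStats:
    """Per-SNP association results for a single trait.

    Attributes
    ----------
    trait:
        Trait identifier.
    table:
        DataFrame with the columns of :data:`REQUIRED_COLUMNS`; one row per
        SNP.
    provenance:
        Free-form metadata (set for factor-level statistics: factor id,
        child ids and the loadings used to combine them).
    """

    trait: str
    table: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(
                f"summary statistics for {self.trait!r} missing columns: {missing}"
            )
        t = self.table
        bad: list[str] = []
        if not (np.asarray(t["se"], float) > 0).all():
            bad.append("se must be > 0")
        p = np.asarray(t["p"], float)
        if not ((p > 0) & (p <= 1)).all():
            bad.append("p must be in (0, 1]")
        eaf = np.asarray(t["eaf"], float)
        if not ((eaf > 0) & (eaf < 1)).all():
            bad.append("eaf must be in (0, 1)")
        if t["snp"].duplicated().any():
            dups = t.loc[t["snp"].duplicated(), "snp"].head(3).tolist()
            bad.append(f"duplicate SNP ids (e.g. {dups})")
        if (np.asarray(t["pos"]) < 0).any():
            bad.append("positions must be non-negative")
        if bad:
            raise ValueError(
                f"invalid summary statistics for {self.trait!r}: " + "; ".join(bad)
            )

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def mean_n(self) -> float:
        return float(np.asarray(self.table["n"], float).mean())

    def z(self) -> np.ndarray:
        """Per-SNP z-scores beta/se."""
        t = self.table
        return np.asarray(t["beta"], float) / np.asarray(t["se"], float)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("snp", drop=False)

    def copy(self) -> "TraitSumStats":
        return TraitSumStats(self.trait, self.table.copy(), dict(self.provenance))


def align_snps(stats: Iterable[TraitSumStats]) -> list[TraitSumStats]:
    """Restrict every table to the shared SNP set, in a common order.

    Raises if the intersection is empty.
    """
    stats = list(stats)
    if not stats:
        return []
    common: pd.Index | None = None
    for s in stats:
        ids = pd.Index(s.table["snp"])
        common = ids if common is None else common.intersection(ids)
    if common is None or len(common) == 0:
        raise ValueError("no SNPs shared across the supplied summary statistics")
    out = []
    for s in stats:
        tab = s.indexed().loc[common].reset_index(drop=True)
        out.append(TraitSumStats(s.trait, tab, dict(s.provenance)))
    return out
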