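"""Pipeline configuration: the single source of truth for every analysis constant.

All thresholds used anywhere in the package (locus gap, significance levels,
fit gates, LD cut-offs, ...) live here as :class:`PipelineConfig` defaults.
Stage functions take them as keyword arguments that default to these values,
so a run is fully described by one config object and no module hard-codes a
threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]


@dataclass
class PipelineConfig:
    """All tunable thresholds and seeds for the pipeline.

    Defaults are the standard thresholds of the multi-trait food-liking
    GWAS design; see docs/methods.md for what each controls.
    """

    # -- association scan ---------------------------------------------------
    maf_min: float = 0.001           # minor-allele-frequency filter (strict >)

    # -- multiple testing ----------------------------------------------------
    genomewide_alpha: float = 5e-8   # conventional genome-wide significance
    variance_share: float = 0.95     # eigen share defining effective tests

    # -- genetic correlation estimation --------------------------------------
    jackknife_blocks: int = 200      # delete-one block jackknife blocks
    h2_intercept: float = 1.0        # null mean chi-square (no confounding)
    bonferroni_alpha: float = 0.05   # base alpha for corrected comparisons

    # -- hierarchical factor model -------------------------------------------
    cfi_min: float = 0.9             # comparative fit index gate (strict >)
    srmr_max: float = 0.1            # SRMR gate (strict <)
    merge_rg: float = 0.9            # factors with rg above this are merged
    max_levels: int = 4              # maximum tree depth above the leaves
    min_group_size: int = 3          # identified single-factor model size
    pair_min_abs_rg: float = 0.05    # form a 2-item factor only above this

    # -- locus definition -----------------------------------------------------
    seed_p: float = 1e-5             # locus seed p-value
    locus_gap: int = 250_000         # bp; strictly larger gaps split loci

    # -- effect decomposition -------------------------------------------------
    dv_corr: float = 0.99            # dummy latent / factor correlation
    clogg_alpha: float = 0.05        # direct-only above this Clogg p

    # -- replication ----------------------------------------------------------
    replication_alpha: float = 0.05  # one-tailed replication threshold
    min_n: int = 10_000              # minimum combined N for testability

    # -- gene prioritization --------------------------------------------------
    ld_r2: float = 0.8               # "strong LD" threshold (strict >)

    # -- synthetic data -------------------------------------------------------
    likert_levels: int = 9           # hedonic-scale points (0 = continuous)
    seed: int = 0

    # -- orchestration --------------------------------------------------------
    stages: dict[str, bool] = field(default_factory=lambda: {
        "synthdata": True,
        "assoc_scan": False,   # summary-level fast path by default
        "gencorr": True,
        "hierarchy": True,
        "locusmap": True,
        "effectflow": True,
        "replication": True,
        "geneprior": True,
    })
    paths: dict[str, str] = field(default_factory=dict)
    dialect: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (0.0 <= self.maf_min < 0.5, "maf_min must be in [0, 0.5)"),
            (0.0 < self.genomewide_alpha < 1.0, "genomewide_alpha must be in (0,1)"),
            (0.0 < self.variance_share <= 1.0, "variance_share must be in (0,1]"),
            (self.jackknife_blocks >= 2, "jackknife_blocks must be >= 2"),
            (0.0 < self.cfi_min <= 1.0, "cfi_min must be in (0,1]"),
            (0.0 < self.srmr_max, "srmr_max must be positive"),
            (0.0 < self.merge_rg <= 1.0, "merge_rg must be in (0,1]"),
            (self.max_levels >= 1, "max_levels must be >= 1"),
            (0.0 < self.seed_p < 1.0, "seed_p must be in (0,1)"),
            (self.locus_gap > 0, "locus_gap must be positive"),
            (0.0 < self.dv_corr < 1.0, "dv_corr must be in (0,1)"),
            (0.0 < self.clogg_alpha < 1.0, "clogg_alpha must be in (0,1)"),
            (0.0 < self.replication_alpha < 1.0, "replication_alpha must be in (0,1)"),
            (self.min_n >= 0, "min_n must be non-negative"),
            (0.0 < self.ld_r2 < 1.0, "ld_r2 must be in (0,1)"),
            (self.likert_levels == 0 or self.likert_levels >= 2,
             "likert_levels must be 0 (continuous) or >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


#: Module-level default configuration; stage functions default to its values.
DEFAULTS = PipelineConfig()
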