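import numpy as np
import pandas as pd
import pytest

from treegwas.sumstats import TraitSumStats


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_517)


def make_sumstats(beta, se, trait="t", n=10_000, pos=None, chrom="1",
                  p=None, snps=None):
    """Small helper to build a valid TraitSumStats from raw arrays."""
    from scipy import stats as sps
    beta = np.asarray(beta, float)
    se = np.broadcast_to(np.asarray(se, float), beta.shape)
    m = len(beta)
    if p is None:
        p = 2 * sps.norm.sf(np.abs(beta / se))
    tab = pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{i + 1}" for i in range(m)],
        "chrom": chrom,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 10_000,
        "ea": "A", "oa": "G", "eaf": 0.3,
        "beta": beta, "se": se,
        "p": np.clip(p, 1e-300, 1.0), "n": n,
    })
    return TraitSumStats(trait, tab)


@pytest.fixture
def make_stats():
    return make_sumstats
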