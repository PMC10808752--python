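import numpy as np
import pandas as pd
import pytest


def make_pairs(bx, sx, by, sy, ids=None, pos=None):
    """Harmonized-pair frame from plain arrays."""
    bx = np.asarray(bx, float)
    k = bx.size
    return pd.DataFrame({
        "variant_id": ids if ids is not None
        else [f"rs{i}" for i in range(k)],
        "chrom": "1",
        "pos": pos if pos is not None else np.arange(k) * 10_000 + 1,
        "beta_exp": bx,
        "se_exp": np.broadcast_to(np.asarray(sx, float), (k,)),
        "pval_exp": 1e-8,
        "beta_out": np.asarray(by, float),
        "se_out": np.broadcast_to(np.asarray(sy, float), (k,)),
        "flipped": False,
        "palindromic": False,
    })


def make_sumstats(variant_id, chrom="1", pos=None, effect_allele="A",
                  other_allele="G", eaf=0.3, beta=0.1, se=0.05, pval=1e-6,
                  n=5000.0):
    """Canonical summary-statistics frame from (broadcastable) columns."""
    variant_id = list(variant_id)
    k = len(variant_id)

    def _col(x):
        arr = np.asarray(x)
        return np.broadcast_to(arr, (k,)).copy() if arr.ndim == 0 \
            else np.asarray(x)

    return pd.DataFrame({
        "variant_id": variant_id,
        "chrom": _col(chrom).astype(str),
        "pos": _col(pos if pos is not None
                    else np.arange(k) * 1000 + 1).astype(np.int64),
        "effect_allele": _col(effect_allele).astype(str),
        "other_allele": _col(other_allele).astype(str),
        "eaf": _col(eaf).astype(float),
        "beta": _col(beta).astype(float),
        "se": _col(se).astype(float),
        "pval": _col(pval).astype(float),
        "n": _col(n).astype(float),
        "ncase": np.nan,
        "ncontrol": np.nan,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
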