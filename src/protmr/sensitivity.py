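"""Heterogeneity (Cochran's Q) and directional pleiotropy (Egger intercept).

Applicability rules: Q needs >= 2 instruments; the Egger intercept test needs
>= 3.  Inapplicable tests yield NA fields (None) with the corresponding
``applicable_*`` flag set to False — never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MRResult, _ivw_core, _arrays, egger

ALPHA = 0.05   # "significant" threshold for heterogeneity/pleiotropy calls


@dataclass
class SensitivityResult:
    n_snps: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    applicable_q: bool = False
    applicable_egger: bool = False


def cochran_q(pairs: pd.DataFrame, ivw_beta: float | None = None
              ) -> SensitivityResult:
    """Cochran's Q over per-variant ratio estimates.

    Q = sum_j w_j (theta_j - beta)^2 with first-order ratio weights
    w_j = (se_out/|beta_exp|)^-2, referred to chi-square with k-1 df.
    ``beta`` defaults to the fixed-effect IVW estimate.
    """
    k = len(pairs)
    if k < 2:
        return SensitivityResult(n_snps=k)
    bx, _, by, sy = _arrays(pairs)
    if ivw_beta is None:
        ivw_beta, _, _ = _ivw_core(bx, by, sy)
    theta = by / bx
    w = (sy / np.abs(bx)) ** -2
    q = float((w * (theta - ivw_beta) ** 2).sum())
    df = k - 1
    return SensitivityResult(n_snps=k, q_stat=q, q_df=df,
                             q_pval=float(stats.chi2.sf(q, df)),
                             applicable_q=True)


def egger_intercept_test(egger_result: MRResult) -> SensitivityResult:
    """Directional-pleiotropy test from a fitted Egger regression.

    Two-sided p for intercept/intercept_se on t with k-2 df.
    """
    k = egger_result.n_snps
    if not egger_result.applicable or "egger_intercept" not in \
            egger_result.extra:
        return SensitivityResult(n_snps=k)
    icpt = egger_result.extra["egger_intercept"]
    se = egger_result.extra["egger_intercept_se"]
    pval = float(2 * stats.t.sf(abs(icpt / se), k - 2)) if se > 0 else 1.0
    return SensitivityResult(n_snps=k, egger_intercept=icpt,
                             intercept_se=se, intercept_pval=pval,
                             applicable_egger=True)


def sensitivity_analysis(pairs: pd.DataFrame,
                         ivw_beta: float | None = None) -> SensitivityResult:
    """Run both tests with their applicability rules and merge the fields."""
    res = cochran_q(pairs, ivw_beta)
    if len(pairs) >= 3:
        e = egger_intercept_test(egger(pairs))
        res.egger_intercept = e.egger_intercept
        res.intercept_se = e.intercept_se
        res.intercept_pval = e.intercept_pval
        res.applicable_egger = e.applicable_egger
    return res
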