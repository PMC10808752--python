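"""Two-sample MR estimators on harmonized summary statistics.

All estimators consume the harmonized pair frame produced by
:func:`protmr.sumstats.harmonize` (columns ``beta_exp``, ``se_exp``,
``beta_out``, ``se_out``) and return effects per 1-SD increase in the
standardized exposure, on the log-odds scale for a binary outcome:

* Wald ratio — single instrument, first-order delta-method SE.
* IVW — inverse-variance-weighted meta-analysis of per-variant ratios,
  equivalently weighted regression through the origin; primary estimator.
  Default SE uses the multiplicative random-effects scaling
  ``max(1, sqrt(Q/(k-1)))``.
* MR-Egger — weighted regression with intercept; slope is the causal
  estimate, intercept measures directional pleiotropy.
* Weighted median — consistent when >= 50% of the weight comes from valid
  instruments; parametric-bootstrap SE.
* Weighted mode — mode of an inverse-variance-weighted kernel density over
  per-variant ratios; parametric-bootstrap SE.

Estimators needing more instruments than supplied return an explicit
not-applicable sentinel (``result.applicable`` is False) rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.96

METHODS = ("wald", "ivw", "egger", "weighted_median", "weighted_mode")


@dataclass
class MRResult:
    """One estimator's output for one protein-outcome pair."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    protein_id: str = ""
    outcome_id: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    @property
    def applicable(self) -> bool:
        return bool(self.extra.get("applicable", True))

    @classmethod
    def not_applicable(cls, method: str, n_snps: int,
                       protein_id: str = "", outcome_id: str = "",
                       reason: str = "") -> "MRResult":
        return cls(method, float("nan"), float("nan"), float("nan"),
                   n_snps, protein_id, outcome_id,
                   {"applicable": False, "reason": reason})


def summarize_effect(beta: float, se: float
                     ) -> tuple[float, tuple[float, float],
                                tuple[float, float]]:
    """(OR, OR 95% CI, beta 95% CI) for a log-odds estimate."""
    if se < 0:
        raise ValueError("se must be >= 0")
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return math.exp(beta), (math.exp(lo), math.exp(hi)), (lo, hi)


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0


def _arrays(pairs: pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return (pairs["beta_exp"].to_numpy(float),
            pairs["se_exp"].to_numpy(float),
            pairs["beta_out"].to_numpy(float),
            pairs["se_out"].to_numpy(float))


def wald_ratio(pair: pd.DataFrame | pd.Series, **ids) -> MRResult:
    """Single-instrument causal estimate beta_out/beta_exp.

    SE by the first-order delta method, se_out/|beta_exp|.
    """
    if isinstance(pair, pd.DataFrame):
        if len(pair) != 1:
            raise ValueError("wald_ratio takes exactly one variant")
        pair = pair.iloc[0]
    bx, by, sy = float(pair["beta_exp"]), float(pair["beta_out"]), \
        float(pair["se_out"])
    if bx == 0:
        raise ZeroDivisionError("undefined Wald ratio: beta_exp is 0")
    beta = by / bx
    se = sy / abs(bx)
    return MRResult("wald", beta, se, _norm_p(beta / se), 1, **ids)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray
              ) -> tuple[float, float, float]:
    """Fixed-effect IVW beta, fixed SE, and Cochran's Q around it."""
    w = 1.0 / sy ** 2
    denom = float((w * bx * bx).sum())
    beta = float((w * bx * by).sum()) / denom
    se_fixed = denom ** -0.5
    theta = by / bx
    wq = (sy / np.abs(bx)) ** -2
    q = float((wq * (theta - beta) ** 2).sum())
    return beta, se_fixed, q


def ivw(pairs: pd.DataFrame, re_scale: str = "multiplicative_random",
        **ids) -> MRResult:
    """Inverse-variance-weighted estimate (weights 1/se_out^2).

    With a single instrument this degenerates to the Wald ratio (recorded in
    ``extra['estimated_by']``).  ``re_scale`` in {"fixed",
    "multiplicative_random"}: the latter multiplies the fixed-effect SE by
    max(1, sqrt(Q/(k-1))).
    """
    if re_scale not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown re_scale {re_scale!r}")
    k = len(pairs)
    if k == 0:
        raise ValueError("ivw needs at least one instrument")
    if k == 1:
        res = wald_ratio(pairs, **ids)
        res.method = "ivw"
        res.extra["estimated_by"] = "wald"
        return res
    bx, _, by, sy = _arrays(pairs)
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    scale = max(1.0, math.sqrt(q / (k - 1))) \
        if re_scale == "multiplicative_random" else 1.0
    se = se_fixed * scale
    res = MRResult("ivw", beta, se, _norm_p(beta / se), k, **ids)
    res.extra.update(q_stat=q, q_df=k - 1, re_scale=re_scale,
                     se_fixed=se_fixed)
    return res


def egger(pairs: pd.DataFrame, **ids) -> MRResult:
    """MR-Egger regression (weighted, with intercept).

    Each pair is first oriented so beta_exp >= 0 (both betas negated where
    needed) — the intercept is only interpretable under this orientation.
    Slope/intercept SEs carry the multiplicative scaling
    max(1, sqrt(RSS_w/(k-2))); p-values use t with k-2 df.  Requires >= 3
    instruments, else returns the not-applicable sentinel.
    """
    k = len(pairs)
    if k < 3:
        return MRResult.not_applicable("egger", k, reason="needs >= 3 IVs",
                                       **ids)
    bx, _, by, sy = _arrays(pairs)
    s = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * s, by * s
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy ** 2).fit()
    sigma2 = float(fit.scale)                       # RSS_w / (k - 2)
    scale = max(1.0, math.sqrt(sigma2))
    # (X'WX)^-1 diagonal: SE before any residual-variance scaling
    bse_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    icpt, slope = float(fit.params[0]), float(fit.params[1])
    icpt_se = float(bse_unscaled[0]) * scale
    slope_se = float(bse_unscaled[1]) * scale
    df = k - 2
    pval = float(2 * stats.t.sf(abs(slope / slope_se), df)) \
        if slope_se > 0 else (1.0 if slope == 0 else 0.0)
    res = MRResult("egger", slope, slope_se, pval, k, **ids)
    res.extra.update(
        egger_intercept=icpt, egger_intercept_se=icpt_se,
        egger_intercept_pval=float(2 * stats.t.sf(abs(icpt / icpt_se), df))
        if icpt_se > 0 else (1.0 if icpt == 0 else 0.0),
        df=df, sigma=math.sqrt(sigma2))
    return res


def _ratio_weights(bx, by, sy):
    theta = by / bx
    w = (sy / np.abs(bx)) ** -2
    return theta, w / w.sum()


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative-midpoint rule."""
    order = np.argsort(theta, kind="mergesort")
    t, ww = theta[order], w[order]
    ww = ww / ww.sum()
    s = np.cumsum(ww) - ww / 2.0
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def _boot_draws(bx, sx, by, sy, n_boot, seed):
    rng = np.random.default_rng(seed)
    bx_b = bx + sx * rng.standard_normal((n_boot, bx.size))
    by_b = by + sy * rng.standard_normal((n_boot, by.size))
    return bx_b, by_b


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0, **ids) -> MRResult:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Requires >= 3 instruments.  The bootstrap resamples beta_exp and
    beta_out from normals centred on their estimates; seed and rep count are
    recorded in ``extra``.
    """
    k = len(pairs)
    if k < 3:
        return MRResult.not_applicable("weighted_median", k,
                                       reason="needs >= 3 IVs", **ids)
    bx, sx, by, sy = _arrays(pairs)
    theta, w = _ratio_weights(bx, by, sy)
    est = _weighted_median(theta, w)
    bx_b, by_b = _boot_draws(bx, sx, by, sy, n_boot, seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        t_i, w_i = _ratio_weights(bx_b[i], by_b[i], sy)
        boots[i] = _weighted_median(t_i, w_i)
    se = float(boots.std(ddof=1))
    res = MRResult("weighted_median", est, se, _norm_p(est / se) if se > 0
                   else 1.0, k, **ids)
    res.extra.update(bootstrap_reps=n_boot, seed=seed)
    return res


MODE_GRID_POINTS = 512


def _mode_estimate(theta: np.ndarray, w: np.ndarray,
                   bandwidth_factor: float) -> float:
    k = theta.size
    sd = float(theta.std(ddof=1))
    mad = float(np.median(np.abs(theta - np.median(theta)))) / 0.6745
    h = bandwidth_factor * 0.9 * min(sd, mad if mad > 0 else sd) \
        * k ** (-1 / 5)
    if h <= 0 or not np.isfinite(h):        # all ratios identical
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h,
                       MODE_GRID_POINTS)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None])
                                        / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(pairs: pd.DataFrame, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0, **ids) -> MRResult:
    """Weighted-mode MR estimate (kernel-density argmax over ratios).

    Gaussian kernel with modified-Silverman bandwidth
    ``bandwidth_factor * 0.9 * min(sd, MAD/0.6745) * k^(-1/5)``; density
    argmax taken over a 512-point grid spanning [min-3h, max+3h].  SE by
    parametric bootstrap.  Requires >= 3 instruments.
    """
    k = len(pairs)
    if k < 3:
        return MRResult.not_applicable("weighted_mode", k,
                                       reason="needs >= 3 IVs", **ids)
    bx, sx, by, sy = _arrays(pairs)
    theta, w = _ratio_weights(bx, by, sy)
    est = _mode_estimate(theta, w, bandwidth_factor)
    bx_b, by_b = _boot_draws(bx, sx, by, sy, n_boot, seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        t_i, w_i = _ratio_weights(bx_b[i], by_b[i], sy)
        boots[i] = _mode_estimate(t_i, w_i, bandwidth_factor)
    se = float(boots.std(ddof=1))
    res = MRResult("weighted_mode", est, se, _norm_p(est / se) if se > 0
                   else 1.0, k, **ids)
    res.extra.update(bootstrap_reps=n_boot, seed=seed,
                     bandwidth_factor=bandwidth_factor)
    return res


def results_frame(results: list[MRResult]) -> pd.DataFrame:
    """Serialize MR results to the flat TSV-ready layout."""
    rows = []
    for r in results:
        rows.append({
            "protein": r.protein_id, "outcome": r.outcome_id,
            "method": r.method, "nsnp": r.n_snps, "beta": r.beta,
            "se": r.se, "or": r.or_ if r.applicable else np.nan,
            "or_lci": r.or_ci[0] if r.applicable else np.nan,
            "or_uci": r.or_ci[1] if r.applicable else np.nan,
            "pval": r.pval,
            "egger_intercept": r.extra.get("egger_intercept", np.nan),
            "egger_intercept_pval": r.extra.get("egger_intercept_pval",
                                                np.nan),
            "seed": r.extra.get("seed", np.nan),
        })
    return pd.DataFrame(rows)
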