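"""MR estimators against independent closed-form / brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protmr.mr import (egger, ivw, summarize_effect, wald_ratio,
                       weighted_median, weighted_mode, _weighted_median)

from conftest import make_pairs


def random_pairs(rng, k, sy_range=(0.01, 0.1)):
    bx = rng.normal(0.3, 0.15, k)
    bx[np.abs(bx) < 0.05] = 0.05
    return make_pairs(bx, rng.uniform(0.01, 0.05, k),
                      rng.normal(0.1, 0.3, k),
                      rng.uniform(*sy_range, k))


def wls_origin_oracle(bx, by, w):
    """Weighted least squares through the origin, straight from the normal
    equations."""
    beta = np.sum(w * bx * by) / np.sum(w * bx * bx)
    se = np.sum(w * bx * bx) ** -0.5
    return beta, se


def wls_intercept_oracle(bx, by, sy):
    """Generic weighted OLS with intercept via explicit matrix algebra,
    with the multiplicative residual scaling floored at 1."""
    X = np.column_stack([np.ones_like(bx), bx])
    W = np.diag(1.0 / sy ** 2)
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    coef = xtwx_inv @ X.T @ W @ by
    resid = by - X @ coef
    sigma2 = float(resid @ W @ resid) / (len(bx) - 2)
    se = np.sqrt(np.diag(xtwx_inv)) * max(1.0, math.sqrt(sigma2))
    return coef, se


class TestWaldRatio:
    def test_hand_algebra(self):
        res = wald_ratio(make_pairs([0.5], [0.05], [0.1], [0.02]))
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.04)

    def test_null_outcome(self):
        res = wald_ratio(make_pairs([0.5], [0.05], [0.0], [0.02]))
        assert res.beta == 0.0
        assert res.pval == pytest.approx(1.0)

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pairs([0.0], [0.05], [0.1], [0.02]))

    def test_matches_delta_method_oracle(self, rng):
        for _ in range(20):
            bx, sx = rng.normal(0.5, 0.2), rng.uniform(0.01, 0.1)
            by, sy = rng.normal(0.1, 0.2), rng.uniform(0.01, 0.1)
            if bx == 0:
                continue
            res = wald_ratio(make_pairs([bx], [sx], [by], [sy]))
            assert res.beta == pytest.approx(by / bx, abs=1e-12)
            assert res.se == pytest.approx(sy / abs(bx), abs=1e-12)


class TestIVW:
    def test_single_pair_equals_wald(self):
        pairs = make_pairs([0.5], [0.05], [0.1], [0.02])
        res = ivw(pairs)
        wald = wald_ratio(pairs)
        assert res.beta == pytest.approx(wald.beta)
        assert res.se == pytest.approx(wald.se)
        assert res.method == "ivw"
        assert res.extra["estimated_by"] == "wald"

    def test_precision_adds_for_identical_pairs(self):
        one = make_pairs([0.5], [0.05], [0.1], [0.02])
        two = make_pairs([0.5, 0.5], [0.05], [0.1, 0.1], [0.02])
        r1, r2 = ivw(one), ivw(two, re_scale="fixed")
        assert r2.beta == pytest.approx(r1.beta)
        assert r2.se == pytest.approx(r1.se / math.sqrt(2))

    def test_matches_wls_origin_oracle(self, rng):
        for _ in range(100):
            pairs = random_pairs(rng, 5)
            res = ivw(pairs, re_scale="fixed")
            beta, se = wls_origin_oracle(pairs["beta_exp"],
                                         pairs["beta_out"],
                                         1 / pairs["se_out"] ** 2)
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_random_effects_scaling(self, rng):
        pairs = random_pairs(rng, 8)
        fixed = ivw(pairs, re_scale="fixed")
        rand = ivw(pairs)
        q, df = rand.extra["q_stat"], rand.extra["q_df"]
        assert rand.beta == pytest.approx(fixed.beta)
        assert rand.se == pytest.approx(
            fixed.se * max(1.0, math.sqrt(q / df)))

    def test_order_invariance(self, rng):
        pairs = random_pairs(rng, 7)
        shuffled = pairs.sample(frac=1, random_state=3).reset_index(
            drop=True)
        assert ivw(pairs).beta == pytest.approx(ivw(shuffled).beta,
                                                abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw(make_pairs([], [], [], []))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.2, 5.0))
    def test_sign_flip_and_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, 6)
        base = ivw(pairs).beta
        # negating both betas of any pair leaves the estimate unchanged
        flipped = pairs.copy()
        flipped.loc[0, ["beta_exp", "beta_out"]] *= -1
        assert ivw(flipped).beta == pytest.approx(base, rel=1e-10)
        # scaling every exposure beta by c rescales the estimate by 1/c
        scaled = pairs.copy()
        scaled["beta_exp"] *= c
        assert ivw(scaled).beta == pytest.approx(base / c, rel=1e-9)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.1 + 0.3 * bx
        res = egger(make_pairs(bx, 0.02, by, 0.05))
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.extra["egger_intercept"] == pytest.approx(0.1,
                                                             abs=1e-10)

    def test_below_three_ivs_is_sentinel(self):
        res = egger(make_pairs([0.5, 0.3], [0.05], [0.1, 0.2], [0.02]))
        assert not res.applicable
        assert res.method == "egger"

    def test_matches_weighted_ols_oracle(self, rng):
        for _ in range(100):
            pairs = random_pairs(rng, 20)
            res = egger(pairs)
            bx = pairs["beta_exp"].to_numpy()
            by = pairs["beta_out"].to_numpy()
            sy = pairs["se_out"].to_numpy()
            s = np.where(bx < 0, -1.0, 1.0)     # same orientation rule
            coef, se = wls_intercept_oracle(bx * s, by * s, sy)
            assert res.beta == pytest.approx(coef[1], abs=1e-10)
            assert res.extra["egger_intercept"] == pytest.approx(
                coef[0], abs=1e-10)
            assert res.se == pytest.approx(se[1], abs=1e-10)
            assert res.extra["egger_intercept_se"] == pytest.approx(
                se[0], abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.01],
                           [1.0, 2.0, 3.0], [0.1])
        res = weighted_median(pairs, n_boot=200, seed=1)
        assert res.beta == pytest.approx(2.0)

    def test_degenerate_all_equal(self):
        pairs = make_pairs([0.5, 0.4, 0.2], [0.01],
                           [0.5 * 1.7, 0.4 * 1.7, 0.2 * 1.7], [0.001])
        res = weighted_median(pairs, n_boot=300, seed=2)
        assert res.beta == pytest.approx(1.7, abs=1e-10)
        assert res.se < 0.05

    def test_brute_force_interpolation_oracle(self, rng):
        def oracle(theta, w):
            idx = np.argsort(theta)
            t, ww = theta[idx], w[idx] / w[idx].sum()
            s = np.cumsum(ww) - ww / 2
            if 0.5 <= s[0]:
                return t[0]
            for j in range(len(t) - 1):
                if s[j] <= 0.5 <= s[j + 1]:
                    frac = (0.5 - s[j]) / (s[j + 1] - s[j])
                    return t[j] + frac * (t[j + 1] - t[j])
            return t[-1]

        for _ in range(50):
            theta = rng.normal(0, 1, 5)
            w = rng.uniform(0.1, 2, 5)
            assert _weighted_median(theta, w) == pytest.approx(
                oracle(theta, w), abs=1e-12)

    def test_within_ratio_range(self, rng):
        pairs = random_pairs(rng, 9)
        theta = pairs["beta_out"] / pairs["beta_exp"]
        res = weighted_median(pairs, n_boot=100, seed=3)
        assert theta.min() <= res.beta <= theta.max()

    def test_two_ivs_sentinel(self):
        assert not weighted_median(
            make_pairs([0.5, 0.3], [0.05], [0.1, 0.2], [0.02])).applicable


class TestWeightedMode:
    def test_all_equal_returns_common_ratio(self):
        pairs = make_pairs([0.5, 0.4, 0.2], [0.01],
                           [0.5 * 0.8, 0.4 * 0.8, 0.2 * 0.8], [0.05])
        res = weighted_mode(pairs, n_boot=100, seed=4)
        assert res.beta == pytest.approx(0.8, abs=1e-9)

    def test_majority_cluster_wins(self):
        pairs = make_pairs([1.0] * 5, [0.01],
                           [1.0, 1.01, 0.99, 5.0, 5.01], [0.5])
        res = weighted_mode(pairs, n_boot=100, seed=5)
        assert res.beta == pytest.approx(1.0, abs=0.1)

    def test_grid_argmax_near_fine_grid_oracle(self, rng):
        import protmr.mr as mrmod
        pairs = random_pairs(rng, 12)
        res = weighted_mode(pairs, n_boot=50, seed=6)
        theta = (pairs["beta_out"] / pairs["beta_exp"]).to_numpy()
        w = (pairs["se_out"] / pairs["beta_exp"].abs()) ** -2
        w = (w / w.sum()).to_numpy()
        k = len(theta)
        sd = theta.std(ddof=1)
        mad = np.median(np.abs(theta - np.median(theta))) / 0.6745
        h = 0.9 * min(sd, mad) * k ** (-0.2)
        fine = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h,
                           10 * mrmod.MODE_GRID_POINTS)
        dens = (w[:, None] * np.exp(
            -0.5 * ((fine[None, :] - theta[:, None]) / h) ** 2)).sum(0)
        oracle = fine[np.argmax(dens)]
        step = (fine[-1] - fine[0]) / mrmod.MODE_GRID_POINTS
        assert abs(res.beta - oracle) <= step


class TestSummarizeEffect:
    def test_or_from_ci_midpoints(self):
        # published log-odds CI midpoints must reproduce the published ORs
        or_, _, _ = summarize_effect((0.095 + 0.208) / 2, 0.01)
        assert round(or_, 2) == 1.16
        or_, _, _ = summarize_effect((-1.067 + -0.46) / 2, 0.01)
        assert round(or_, 3) == 0.466

    def test_null_effect(self):
        or_, or_ci, ci = summarize_effect(0.0, 0.1)
        assert or_ == 1.0
        assert ci[0] == pytest.approx(-ci[1])
        assert or_ci[0] * or_ci[1] == pytest.approx(1.0)

    def test_consistent_with_result_properties(self, rng):
        pairs = random_pairs(rng, 4)
        res = ivw(pairs)
        or_, or_ci, ci = summarize_effect(res.beta, res.se)
        assert res.or_ == pytest.approx(or_)
        assert res.or_ci == pytest.approx(or_ci)
        assert (res.ci_low, res.ci_high) == pytest.approx(ci)
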