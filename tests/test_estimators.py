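"""Two-sample MR estimators against independent oracles and identities."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediation.estimators import (
    EstimatorError,
    _weighted_median,
    cochran_q,
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrmediation.sumstats import HarmonizedSet

from conftest import random_harmonized


def weighted_median_oracle(ratios, weights):
    """Loop-based re-statement of the midpoint interpolation rule."""
    order = sorted(range(len(ratios)), key=lambda i: ratios[i])
    r = [ratios[i] for i in order]
    w = [weights[i] for i in order]
    total = sum(w)
    w = [x / total for x in w]
    cum = []
    acc = 0.0
    for wi in w:
        acc += wi
        cum.append(acc - wi / 2.0)
    if cum[0] >= 0.5:
        return r[0]
    for i in range(1, len(r)):
        if cum[i] >= 0.5:
            t = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
            return r[i - 1] + t * (r[i] - r[i - 1])
    return r[-1]


class TestWaldRatio:
    def test_simple_ratio(self):
        est = wald_ratio(0.1, 0.2, 0.01, 0.05)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_null_outcome(self):
        est = wald_ratio(0.1, 0.0, 0.01, 0.05)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.5)

    def test_zero_exposure_rejected(self):
        with pytest.raises(EstimatorError):
            wald_ratio(0.0, 0.2, 0.01, 0.05)

    def test_first_order_se_matches_monte_carlo(self, rng):
        """With a strong instrument (|bx|/se_x = 25) the simulated spread
        of by/bx matches the first-order SE within 5%."""
        bx, se_x, by, se_y = 0.5, 0.02, 0.1, 0.05
        draws = 1_000_000
        num = by + rng.standard_normal(draws) * se_y
        den = bx + rng.standard_normal(draws) * se_x
        mc_sd = np.std(num / den)
        assert mc_sd == pytest.approx(se_y / abs(bx), rel=0.05)


class TestIvw:
    def test_degenerate_homogeneity(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = HarmonizedSet.from_arrays(bx, 0.01 * bx, 1.7 * bx, [0.02] * 3)
        est = ivw(h)
        assert est.beta == pytest.approx(1.7, rel=1e-12)
        q = cochran_q(h, est)
        assert q.q == pytest.approx(0.0, abs=1e-18)
        assert q.pvalue == pytest.approx(1.0)

    def test_single_variant_rejected(self):
        h = HarmonizedSet.from_arrays([0.1], [0.01], [0.2], [0.02])
        with pytest.raises(EstimatorError, match="wald_ratio"):
            ivw(h)

    @pytest.mark.parametrize("k", range(2, 11))
    def test_matches_wls_oracle(self, k, rng):
        """IVW equals a statsmodels zero-intercept WLS solve to 1e-12."""
        h = random_harmonized(rng, k)
        est = ivw(h, model="fixed")
        fit = sm.WLS(h.by(), h.bx(), weights=1.0 / h.sy() ** 2).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-12)

    def test_fixed_se_never_exceeds_random_effects_se(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, 8)
            assert ivw(h, "fixed").se <= ivw(h, "multiplicative_random").se + 1e-15

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(EstimatorError):
            ivw(random_harmonized(rng, 5), model="additive")


class TestWeightedMedian:
    def test_equal_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = HarmonizedSet.from_arrays(bx, 0.01 * bx, 2.0 * bx, [0.02] * 3)
        est = weighted_median(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, rel=1e-12)

    def test_three_snp_equal_weights(self):
        # ratios {1, 2, 9}: cumulative midpoints hit 0.5 exactly at the middle
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.1, 0.2, 0.9])
        h = HarmonizedSet.from_arrays(bx, [0.01] * 3, by, [0.02] * 3)
        est = weighted_median(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, rel=1e-12)

    def test_two_point_interpolation(self):
        # 50% weight at ratio 0 and 50% at ratio 4 -> midpoint 2; a third
        # negligible-weight variant satisfies the k >= 3 precondition
        ratios = np.array([0.0, 4.0, 4.0])
        weights = np.array([0.499999, 0.499999, 2e-6])
        assert _weighted_median(ratios, weights)[0] == pytest.approx(2.0, abs=1e-4)

    def test_matches_bruteforce_on_small_instruments(self, rng):
        """Exhaustive sweep of small instruments (k = 3..5) against the
        loop-based oracle."""
        for _ in range(300):
            k = int(rng.integers(3, 6))
            ratios = rng.normal(0, 3, size=k)
            weights = rng.uniform(0.1, 2.0, size=k)
            ours = _weighted_median(ratios, weights)[0]
            assert ours == pytest.approx(
                weighted_median_oracle(list(ratios), list(weights)), rel=1e-12
            )

    def test_duplication_near_invariance(self, rng):
        """Duplicating every variant (weights renormalized) leaves the
        estimate essentially unchanged.  Exact invariance does not hold
        for the midpoint-interpolation convention — duplication shifts the
        interpolation knots — so the check allows interpolation wiggle
        bounded by the local ratio spacing."""
        for _ in range(10):
            h = random_harmonized(rng, 6)
            ratios = np.sort(h.by() / h.bx())
            gap = np.max(np.diff(ratios))
            est1 = weighted_median(h, n_boot=10, seed=1)
            doubled = HarmonizedSet.from_arrays(
                np.tile(h.bx(), 2), np.tile(h.sx(), 2),
                np.tile(h.by(), 2), np.tile(h.sy(), 2),
            )
            est2 = weighted_median(doubled, n_boot=10, seed=1)
            assert abs(est1.beta - est2.beta) <= gap / 2 + 1e-12

    def test_negative_boot_rejected(self, rng):
        with pytest.raises(EstimatorError):
            weighted_median(random_harmonized(rng, 5), n_boot=0)


class TestEgger:
    def test_matches_wls_oracle(self, rng):
        """Slope and intercept equal an independent weighted with-intercept
        solve; SEs match after the residual-inflation floor."""
        h = random_harmonized(rng, 5)
        res = mr_egger(h)
        X = sm.add_constant(h.bx())
        fit = sm.WLS(h.by(), X, weights=1.0 / h.sy() ** 2).fit()
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        sigma = math.sqrt(fit.scale)
        expected_se = fit.bse[1] * max(1.0, sigma) / sigma
        assert res.slope.se == pytest.approx(expected_se, rel=1e-10)

    def test_constant_outcome_shift_moves_intercept_only(self, rng):
        h = random_harmonized(rng, 8)
        res1 = mr_egger(h)
        shifted = HarmonizedSet.from_arrays(
            h.bx(), h.sx(), h.by() + 0.05, h.sy()
        )
        res2 = mr_egger(shifted)
        assert res2.intercept - res1.intercept == pytest.approx(0.05, rel=1e-8)
        assert res2.slope.beta == pytest.approx(res1.slope.beta, rel=1e-8)

    def test_orientation_invariance(self, rng):
        """Flipping the allele coding of some variants does not change the
        estimate (rows are re-oriented to non-negative exposure betas)."""
        h = random_harmonized(rng, 10)
        res1 = mr_egger(h)
        sign = np.where(np.arange(10) % 2 == 0, -1.0, 1.0)
        flipped = HarmonizedSet.from_arrays(
            h.bx() * sign, h.sx(), h.by() * sign, h.sy()
        )
        res2 = mr_egger(flipped)
        assert res2.slope.beta == pytest.approx(res1.slope.beta, rel=1e-10)
        assert res2.intercept == pytest.approx(res1.intercept, rel=1e-10)

    def test_too_few_variants(self, rng):
        with pytest.raises(EstimatorError):
            mr_egger(random_harmonized(rng, 2))

    def test_slope_equals_ivw_when_intercept_constrained(self, rng):
        """Dropping the intercept from the Egger design reproduces IVW —
        verified with a constrained refit."""
        h = random_harmonized(rng, 7)
        fit = sm.WLS(h.by(), h.bx(), weights=1.0 / h.sy() ** 2).fit()
        assert ivw(h, "fixed").beta == pytest.approx(fit.params[0], rel=1e-12)


class TestCochranQ:
    def test_symmetric_two_point(self):
        # unit weights, ratios at b +/- d: Q = 2 d^2
        d = 0.7
        bx = np.array([1.0, 1.0])
        by = np.array([1.0 + d, 1.0 - d])
        h = HarmonizedSet.from_arrays(bx, [0.01] * 2, by, [1.0, 1.0])
        est = ivw(h, model="fixed")
        q = cochran_q(h, est)
        assert q.q == pytest.approx(2 * d * d, rel=1e-10)
        assert q.df == 1

    def test_homogeneous_simulation_q_near_df(self, rng):
        """Under homogeneity E[Q] = k - 1 (chi-square calibration)."""
        k, reps = 20, 300
        stats = []
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.3, size=k)
            sy = np.full(k, 0.05)
            by = 0.4 * bx + rng.standard_normal(k) * sy
            h = HarmonizedSet.from_arrays(bx, [0.001] * k, by, sy)
            stats.append(cochran_q(h, ivw(h, "fixed")).q / (k - 1))
        assert np.mean(stats) == pytest.approx(1.0, abs=0.05)


class TestOddsRatioConversion:
    def test_null_effect(self):
        assert to_odds_ratio(0.0, "binary") == pytest.approx(1.0)
        assert to_odds_ratio(0.0, "continuous") == pytest.approx(1.0)

    def test_binary_doubling_scale(self):
        assert to_odds_ratio(1.0, "binary") == pytest.approx(2.0, rel=1e-12)

    def test_continuous_per_sd_scale(self):
        assert to_odds_ratio(1.0, "continuous") == pytest.approx(math.e, rel=1e-12)

    def test_monotone_and_order_preserving(self):
        or_, lo, hi = to_odds_ratio(0.3, "binary", ci=(0.1, 0.5))
        assert lo < or_ < hi
        assert to_odds_ratio(0.4, "binary") > to_odds_ratio(0.3, "binary")

    def test_unknown_type_rejected(self):
        with pytest.raises(EstimatorError):
            to_odds_ratio(0.1, "ordinal")
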