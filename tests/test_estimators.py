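"""MR estimators: closed forms, oracle cross-checks, invariances, rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eqtlmr import (egger, ivw, rescale_to_relative_reduction, wald_ratio,
                    weighted_median)
from conftest import make_pair, make_set


def random_set(rng, k=10, slope=0.3):
    bx = rng.uniform(0.02, 0.1, k) * rng.choice([-1, 1], k)
    sy = rng.uniform(0.005, 0.02, k)
    by = slope * bx + rng.normal(0, sy)
    return make_set(bx, by, sy)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(make_pair("rs1", 0.5, 0.01, 0.1, 0.05))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(make_pair("rs1", 0.5, 0.01, 0.0, 0.05)).beta == 0.0

    def test_zero_exposure_beta_fatal(self):
        with pytest.raises(ValueError):
            wald_ratio(make_pair("rs1", 0.0, 0.01, 0.1, 0.05))


class TestIVW:
    def test_consensus_ratio(self):
        hs = make_set([0.5, 1.0], [0.1, 0.2], [0.05, 0.05])
        assert ivw(hs).beta == pytest.approx(0.2)

    def test_hand_evaluated_closed_form(self):
        # w = 100 each: (100*0.1 + 100*2*0.4) / (100*1 + 100*4) = 90/500
        hs = make_set([1.0, 2.0], [0.1, 0.4], [0.1, 0.1])
        assert ivw(hs).beta == pytest.approx(0.18)

    def test_single_variant_equals_wald(self):
        hs = make_set([0.4], [0.1], [0.02])
        w = wald_ratio(hs.pairs[0])
        est = ivw(hs)
        assert est.beta == w.beta and est.se == w.se

    def test_empty_set_fatal(self):
        with pytest.raises(ValueError):
            ivw(make_set([], [], []))

    def test_closed_form_to_1e12_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            hs = random_set(rng, k=int(rng.integers(2, 15)))
            bx, _, by, sy = hs.arrays()
            w = 1 / sy ** 2
            expected = np.sum(w * bx * by) / np.sum(w * bx ** 2)
            assert abs(ivw(hs).beta - expected) < 1e-12

    def test_matches_statsmodels_wls_through_origin(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        hs = random_set(rng)
        bx, _, by, sy = hs.arrays()
        fit = sm.WLS(by, bx[:, None], weights=1 / sy ** 2).fit()
        est = ivw(hs)
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
        # fixed-effect SE = statsmodels unscaled covariance
        assert est.se == pytest.approx(
            float(np.sqrt(fit.cov_params(scale=1.0)[0, 0])), rel=1e-10)

    def test_mre_se_never_below_fixed(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            hs = random_set(rng)
            assert ivw(hs, "multiplicative_random").se >= ivw(hs).se - 1e-15


class TestEgger:
    def test_exact_fit_recovers_line(self):
        bx = np.array([0.02, 0.04, 0.06, 0.08, 0.10])
        by = 0.02 + 0.3 * bx
        hs = make_set(bx, by, [0.01] * 5)
        slope, intercept = egger(hs)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)

    def test_requires_three_variants(self):
        with pytest.raises(ValueError, match="3"):
            egger(make_set([0.1, 0.2], [0.05, 0.04], [0.01, 0.01]))

    def test_matches_statsmodels_wls_after_orientation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        hs = random_set(rng)
        bx, _, by, sy = hs.arrays()
        sgn = np.sign(bx)
        X = sm.add_constant(np.abs(bx))
        fit = sm.WLS(sgn * by, X, weights=1 / sy ** 2).fit()
        slope, intercept = egger(hs)
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_directional_pleiotropy_shifts_intercept(self):
        # every variant's outcome beta shifted by +0.05: the intercept should
        # absorb the shift and the slope stay near the true value
        rng = np.random.default_rng(4)
        shifts = []
        for _ in range(100):
            bx = rng.uniform(0.02, 0.1, 13)
            sy = np.full(13, 0.01)
            by = 0.3 * bx + 0.05 + rng.normal(0, sy)
            _, intercept = egger(make_set(bx, by, sy))
            shifts.append(intercept.beta)
        assert np.mean(shifts) == pytest.approx(0.05, abs=0.01)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        hs = make_set([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.05, 0.05, 0.05])
        assert weighted_median(hs, n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_majority_weight_variant_wins(self):
        # middle variant carries ~60% of normalized weight via tiny outcome SE
        hs = make_set([0.1, 0.1, 0.1, 0.1],
                      [0.05, 0.02, 0.001, 0.04],
                      [0.1, 0.013, 0.1, 0.1])
        bx, _, _, sy = hs.arrays()
        w = bx ** 2 / sy ** 2
        assert w[1] / w.sum() > 0.5
        assert weighted_median(hs, n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_exact_boundary_interpolates(self):
        hs = make_set([0.1, 0.1], [0.01, 0.03], [0.05, 0.05])
        with pytest.raises(ValueError):
            weighted_median(hs, n_boot=10, seed=0)  # k >= 3 required
        hs = make_set([0.1, 0.1, 0.1, 0.1],
                      [0.01, 0.02, 0.03, 0.04],
                      [0.05, 0.05, 0.05, 0.05])
        # equal weights, even k: cumulative weight hits 0.5 exactly between
        # the 2nd and 3rd ordered ratios
        assert weighted_median(hs, n_boot=10, seed=0).beta == pytest.approx(0.25)

    def test_bootstrap_deterministic_given_seed(self, default_study):
        _, hs = default_study
        a = weighted_median(hs, n_boot=200, seed=11)
        b = weighted_median(hs, n_boot=200, seed=11)
        assert a.se == b.se

    def test_bootstrap_se_stabilizes(self, default_study):
        _, hs = default_study
        se1 = weighted_median(hs, n_boot=1000, seed=5).se
        se2 = weighted_median(hs, n_boot=2000, seed=5).se
        assert abs(se2 - se1) / se1 < 0.05

    def test_robust_to_minority_invalid_instruments(self):
        # 5 of 13 variants get large directional pleiotropy; the weighted
        # median should beat IVW on median absolute error
        rng = np.random.default_rng(6)
        err_wm, err_ivw = [], []
        for rep in range(100):
            bx = rng.uniform(0.03, 0.1, 13)
            sy = np.full(13, 0.01)
            by = 0.3 * bx + rng.normal(0, sy)
            by[:5] += 0.05
            hs = make_set(bx, by, sy)
            err_wm.append(abs(weighted_median(hs, n_boot=50, seed=rep).beta - 0.3))
            err_ivw.append(abs(ivw(hs).beta - 0.3))
        assert np.median(err_wm) < np.median(err_ivw)


class TestJointSignFlipInvariance:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=4, max_size=12))
    def test_estimators_invariant(self, flips):
        rng = np.random.default_rng(len(flips) * 7 + sum(flips))
        hs = random_set(rng, k=len(flips))
        flipped = make_set(
            [(-1 if f else 1) * p.beta_exposure for f, p in zip(flips, hs.pairs)],
            [(-1 if f else 1) * p.beta_outcome for f, p in zip(flips, hs.pairs)],
            [p.se_outcome for p in hs.pairs],
            [p.se_exposure for p in hs.pairs])
        assert ivw(flipped).beta == pytest.approx(ivw(hs).beta, abs=1e-12)
        assert egger(flipped)[0].beta == pytest.approx(egger(hs)[0].beta,
                                                       abs=1e-12)
        assert weighted_median(flipped, n_boot=10, seed=0).beta == \
            pytest.approx(weighted_median(hs, n_boot=10, seed=0).beta, abs=1e-12)


class TestRescaling:
    def test_small_fraction_limit(self):
        est = ivw(make_set([0.5, 1.0], [0.1, 0.2], [0.05, 0.05]))
        out = rescale_to_relative_reduction(est, 1e-9)
        assert abs(out.beta) < 1e-8

    def test_unit_scale_at_one_minus_inv_e(self):
        est = ivw(make_set([0.5, 1.0], [0.1, 0.2], [0.05, 0.05]))
        out = rescale_to_relative_reduction(est, 1 - math.exp(-1))
        assert out.beta == pytest.approx(-est.beta)
        assert out.se == pytest.approx(est.se)

    def test_34_percent_scale_factor(self):
        est = ivw(make_set([0.5, 1.0], [0.1, 0.2], [0.05, 0.05]))
        out = rescale_to_relative_reduction(est, 0.34)
        assert out.beta / -est.beta == pytest.approx(math.log(1 / 0.66))
        assert out.beta / -est.beta == pytest.approx(0.4155, abs=2e-4)

    def test_invalid_fraction_fatal(self):
        est = ivw(make_set([0.5], [0.1], [0.05]))
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                rescale_to_relative_reduction(est, bad)
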