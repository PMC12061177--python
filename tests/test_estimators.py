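import math

import numpy as np
import pytest

from mrkit.estimators import (cml_ma, ivw, mr_egger, wald_ratio,
                              weighted_median)
from mrkit.exceptions import (EstimationError, InsufficientInstrumentsError)
from mrkit.harmonize import HarmonizedSet

from conftest import make_hset


class TestWaldRatio:
    def test_arithmetic(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.02])
        est = wald_ratio(hs.pairs[0])
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        hs = make_hset([0.1], [0.01], [0.0], [0.02])
        assert wald_ratio(hs.pairs[0]).beta == 0.0

    def test_negative_exposure_effect_sign(self):
        hs = make_hset([-0.1], [0.01], [0.05], [0.02])
        est = wald_ratio(hs.pairs[0])
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_effect_undefined(self):
        hs = make_hset([0.0], [0.01], [0.05], [0.02])
        with pytest.raises(EstimationError):
            wald_ratio(hs.pairs[0])


class TestIVW:
    def test_closed_form_two_snps(self):
        # ratios 0.5 (se 0.2) and 0.3 (se 0.1): w = 25, 100
        hs = make_hset([0.1, 0.1], [0.01, 0.01], [0.05, 0.03], [0.02, 0.01])
        est = ivw(hs, mode="fe")
        assert est.beta == pytest.approx((0.5 * 25 + 0.3 * 100) / 125)
        assert est.se == pytest.approx(1 / math.sqrt(125))
        assert est.se == pytest.approx(0.08944, abs=5e-6)

    def test_identical_ratios_q_zero_mre_equals_fe(self):
        hs = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20],
                       [0.01, 0.02, 0.04])
        fe, mre = ivw(hs, "fe"), ivw(hs, "mre")
        assert fe.beta == pytest.approx(0.5)
        assert mre.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(fe.se)

    def test_single_pair_reduces_to_wald(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.02])
        est = ivw(hs)
        wald = wald_ratio(hs.pairs[0])
        assert est.beta == wald.beta and est.se == wald.se
        assert est.extra["fallback"] == "wald"

    def test_empty_errors(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(HarmonizedSet([]))


class TestMREgger:
    def test_exact_affine_fit(self):
        be = np.array([0.05, 0.10, 0.15, 0.20])
        bo = 0.02 + 0.4 * be
        hs = make_hset(be, [0.01] * 4, bo, [0.01, 0.012, 0.014, 0.016])
        est = mr_egger(hs)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.02, abs=1e-12)
        assert est.extra["rss_w"] == pytest.approx(0.0, abs=1e-18)

    def test_proportional_through_origin(self):
        be = np.array([0.05, 0.10, 0.15])
        hs = make_hset(be, [0.01] * 3, 0.7 * be, [0.01] * 3)
        est = mr_egger(hs)
        assert est.beta == pytest.approx(0.7, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.0, abs=1e-14)

    def test_orientation_invariance(self):
        """Flipping the allele coding of some SNPs (negating both effects)
        leaves the Egger fit unchanged."""
        be = np.array([0.05, 0.10, 0.15, 0.20])
        bo = 0.02 + 0.4 * be + np.array([1e-3, -2e-3, 0.0, 1e-3])
        hs1 = make_hset(be, [0.01] * 4, bo, [0.01] * 4)
        sign = np.array([1, -1, 1, -1])
        hs2 = make_hset(be * sign, [0.01] * 4, bo * sign, [0.01] * 4)
        e1, e2 = mr_egger(hs1), mr_egger(hs2)
        assert e1.beta == pytest.approx(e2.beta)
        assert e1.extra["intercept"] == pytest.approx(e2.extra["intercept"])

    def test_too_few_instruments(self):
        hs = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hs)

    def test_directional_pleiotropy_recovered_in_mean(self):
        """With a constant pleiotropic offset on every SNP, the intercept
        estimates that offset and the slope the causal effect."""
        rng = np.random.default_rng(5)
        intercepts = []
        for _ in range(100):
            be = np.abs(rng.normal(0.1, 0.03, 20))
            bo = 0.05 + 0.3 * be + rng.normal(0, 0.005, 20)
            hs = make_hset(be, [0.01] * 20, bo, [0.005] * 20)
            intercepts.append(mr_egger(hs).extra["intercept"])
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.005)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        hs = make_hset([0.1] * 3, [0.01] * 3, [0.02, 0.05, 0.09], [0.01] * 3)
        est = weighted_median(hs, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_dominant_weight(self):
        # middle SNP carries ~98% of the weight via a tiny outcome se
        hs = make_hset([0.1] * 3, [0.01] * 3, [0.02, 0.05, 0.09],
                       [0.07, 0.001, 0.07])
        est = weighted_median(hs, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.02)

    def test_seed_reproducibility(self):
        hs = make_hset([0.1, 0.12, 0.09, 0.11], [0.01] * 4,
                       [0.05, 0.05, 0.04, 0.06], [0.01] * 4)
        a = weighted_median(hs, seed=7)
        b = weighted_median(hs, seed=7)
        assert a.se == b.se

    def test_too_few_instruments(self):
        hs = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(hs, seed=1)


class TestCMLMA:
    def test_clean_limit_all_weight_on_k0(self):
        be = np.array([0.05, 0.10, 0.15, 0.20, 0.25])
        hs = make_hset(be, [1e-4] * 5, 0.3 * be, [1e-4] * 5)
        est = cml_ma(hs)
        assert est.beta == pytest.approx(0.3, abs=1e-4)
        # zero deviance at every K: weights decay purely via the K*log(L)
        # penalty, so K=0 carries the single largest weight
        w = est.extra["bic_weights"]
        assert w[0] == max(w.values())
        assert est.extra["k_best"] == 0

    def test_planted_gross_pleiotropy_identified(self):
        rng = np.random.default_rng(11)
        be = np.abs(rng.normal(0.1, 0.02, 12))
        bo = 0.2 * be + rng.normal(0, 0.002, 12)
        bo[3] += 0.08  # gross direct effect on one SNP
        hs = make_hset(be, [0.005] * 12, bo, [0.002] * 12)
        est = cml_ma(hs)
        assert est.extra["k_best"] == 1
        assert est.extra["invalid_ids"] == ["rs004"]
        assert est.beta == pytest.approx(0.2, abs=0.01)

    def test_k0_matches_ivw_fixed_as_exposure_noise_vanishes(self):
        rng = np.random.default_rng(3)
        be = np.abs(rng.normal(0.1, 0.03, 10))
        bo = 0.25 * be + rng.normal(0, 0.01, 10)
        so = rng.uniform(0.005, 0.02, 10)
        hs = make_hset(be, [1e-6] * 10, bo, so)
        est = cml_ma(hs, k_grid=[0])
        fe = ivw(hs, mode="fe")
        assert est.beta == pytest.approx(fe.beta, abs=1e-4)
        assert est.se == pytest.approx(fe.se, abs=1e-4)

    def test_k_grid_validation(self):
        hs = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.01] * 3)
        with pytest.raises(ValueError):
            cml_ma(hs, k_grid=[5])


class TestSharedInvariants:
    def _noisy_hset(self, rng, L=8):
        be = np.abs(rng.normal(0.1, 0.03, L))
        bo = 0.2 * be + rng.normal(0, 0.01, L)
        return be, bo

    @pytest.mark.parametrize("fit", [
        lambda h: ivw(h),
        lambda h: mr_egger(h),
        lambda h: weighted_median(h, seed=5),
        lambda h: cml_ma(h),
    ], ids=["ivw", "egger", "wmedian", "cml"])
    def test_reorder_invariance(self, rng, fit):
        be, bo = self._noisy_hset(rng)
        hs = make_hset(be, [0.01] * 8, bo, [0.01] * 8)
        perm = rng.permutation(8)
        hs_p = HarmonizedSet([hs.pairs[i] for i in perm])
        assert fit(hs).beta == pytest.approx(fit(hs_p).beta, rel=1e-9)

    @pytest.mark.parametrize("fit", [
        lambda h: ivw(h),
        lambda h: mr_egger(h),
        lambda h: weighted_median(h, seed=5),
        lambda h: cml_ma(h),
    ], ids=["ivw", "egger", "wmedian", "cml"])
    def test_sign_equivariance(self, rng, fit):
        """Negating both sides leaves beta unchanged; negating only the
        outcome negates beta."""
        be, bo = self._noisy_hset(rng)
        hs = make_hset(be, [0.01] * 8, bo, [0.01] * 8)
        hs_both = make_hset(-be, [0.01] * 8, -bo, [0.01] * 8)
        hs_out = make_hset(be, [0.01] * 8, -bo, [0.01] * 8)
        b = fit(hs).beta
        assert fit(hs_both).beta == pytest.approx(b, rel=1e-7, abs=1e-9)
        assert fit(hs_out).beta == pytest.approx(-b, rel=1e-7, abs=1e-9)

    def test_ci_is_normal_theory(self):
        hs = make_hset([0.1, 0.12, 0.09], [0.01] * 3, [0.05, 0.05, 0.04],
                       [0.01] * 3)
        est = ivw(hs)
        assert est.ci_low == pytest.approx(est.beta - 1.959963984540054 * est.se)
        assert est.ci_high == pytest.approx(est.beta + 1.959963984540054 * est.se)
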