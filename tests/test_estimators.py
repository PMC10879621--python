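"""MR estimators: exact micro-checks, independent oracles, key properties."""

import numpy as np
import pytest

from mrmediation import (InsufficientInstrumentsError, ivw, make_table,
                         mode_estimate, mr_egger, smr, wald_ratio,
                         weighted_median)
from mrmediation.estimators import _weighted_median_1d
from mrmediation.sumstats import SummaryStatRecord

from conftest import random_mr_table


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        r = wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert r.ratio == pytest.approx(2.0)
        assert r.se_ratio == pytest.approx(0.5)
        assert r.weight == pytest.approx(4.0)

    def test_zero_numerator(self):
        r = wald_ratio(0.1, 0.02, 0.0, 0.05)
        assert r.ratio == 0.0 and r.se_ratio == pytest.approx(0.5)

    def test_second_order_se(self):
        r = wald_ratio(0.1, 0.02, 0.2, 0.05, order="second")
        assert r.se_ratio == pytest.approx(np.sqrt(0.25 + 0.16))

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError, match="rs9"):
            wald_ratio(0.0, 0.02, 0.2, 0.05, snp_id="rs9")


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        t = make_table([0.1], [0.02], [0.2], [0.05])
        est = ivw(t)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_equal_weights_give_arithmetic_mean(self, equal_se_table):
        est = ivw(equal_se_table, model="fixed")
        assert est.beta == pytest.approx(1.0)
        assert est.se == pytest.approx(1 / np.sqrt(12))
        assert est.extra["q"] == pytest.approx(2.0)

    def test_random_effects_scale_floored_at_one(self, equal_se_table):
        est = ivw(equal_se_table)
        # Q/(J-1) = 1 exactly, so the multiplicative scale stays 1
        assert est.extra["scale"] == pytest.approx(1.0)
        assert est.se == pytest.approx(1 / np.sqrt(12))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_through_origin(self, seed):
        t = random_mr_table(np.random.default_rng(seed))
        bx, by = t["beta_exp"].to_numpy(), t["beta_out"].to_numpy()
        w = t["se_out"].to_numpy() ** -2.0
        slope = (w * bx * by).sum() / (w * bx * bx).sum()
        se = ((w * bx * bx).sum()) ** -0.5
        est = ivw(t, model="fixed")
        assert est.beta == pytest.approx(slope, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_or_and_ci_are_exp_transform(self, equal_se_table):
        est = ivw(equal_se_table)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.or_ < est.ci_high


class TestEgger:
    def test_exact_collinear_fit(self):
        t = make_table([1, 2, 3], [0.1] * 3, [1, 2, 3], [0.5] * 3)
        est = mr_egger(t)
        assert est.beta == pytest.approx(1.0)
        assert est.extra["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_offset_line(self):
        t = make_table([1, 2, 3], [0.1] * 3, [1, 3, 5], [0.5] * 3)
        est = mr_egger(t)
        assert est.beta == pytest.approx(2.0)
        assert est.extra["intercept"] == pytest.approx(-1.0)
        assert est.extra["rss"] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        t = random_mr_table(np.random.default_rng(100 + seed), j=20)
        bx, by = t["beta_exp"].to_numpy(), t["beta_out"].to_numpy()
        flip = np.sign(bx)
        x, y = bx * flip, by * flip
        w = t["se_out"].to_numpy() ** -2.0
        # independent solve: weighted lstsq via sqrt-weight design
        A = np.sqrt(w)[:, None] * np.column_stack([np.ones_like(x), x])
        b = np.sqrt(w) * y
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        est = mr_egger(t)
        assert est.extra["intercept"] == pytest.approx(coef[0], abs=1e-10)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)

    def test_too_few_snps(self):
        t = make_table([1, 2], [0.1] * 2, [1, 2], [0.5] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(t)


class TestWeightedMedian:
    def test_equal_weight_median_hit_exactly(self):
        t = make_table([1, 1, 1], [0.1] * 3, [1.0, 2.0, 5.0], [1.0] * 3)
        est = weighted_median(t, n_boot=200, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_standardized_cumulative_weights(self):
        p_expected = np.array([1 / 6, 3 / 6, 5 / 6])
        r = np.array([1.0, 2.0, 5.0])
        w = np.ones(3)
        s = np.cumsum(w)
        p = (s - w / 2) / s[-1]
        assert np.allclose(p, p_expected)
        assert _weighted_median_1d(r, w) == pytest.approx(2.0)

    def test_constant_ratios(self):
        t = make_table([1, 1, 1], [0.01] * 3, [0.7, 0.7, 0.7], [0.02] * 3)
        est = weighted_median(t, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.7)
        assert 0 < est.se < 0.1

    def test_bootstrap_reproducible(self, equal_se_table):
        a = weighted_median(equal_se_table, n_boot=100, seed=9)
        b = weighted_median(equal_se_table, n_boot=100, seed=9)
        assert a.se == b.se

    def test_seed_is_mandatory(self, equal_se_table):
        with pytest.raises(ValueError):
            weighted_median(equal_se_table)


class TestMode:
    def test_dominant_atom_resists_outlier(self):
        t = make_table([1] * 4, [0.01] * 4, [0.5, 0.5, 0.5, 4.0], [0.05] * 4)
        est = mode_estimate(t, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_symmetric_ratios_mode_at_zero(self):
        t = make_table([1, 1, 1], [0.01] * 3, [-1.0, 0.0, 1.0], [0.5] * 3)
        est = mode_estimate(t, n_boot=50, seed=0)
        # exact symmetry up to the 512-point grid resolution
        assert est.beta == pytest.approx(0.0, abs=0.02)

    def test_bimodal_simple_mode_finds_major_component(self):
        rng = np.random.default_rng(2)
        r = np.concatenate([rng.normal(0.4, 0.05, 12), rng.normal(2.0, 0.05, 8)])
        t = make_table(np.ones(20), [0.01] * 20, r, [0.05] * 20)
        est = mode_estimate(t, n_boot=50, seed=0)
        sd = np.std(r, ddof=1)
        iqr = np.subtract(*np.percentile(r, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * 20 ** -0.2
        assert abs(est.beta - 0.4) < h / 2


class TestSMR:
    def make(self, beta, se):
        return SummaryStatRecord("rs1", "1", 1, "A", "G", 0.3, beta, se, 1e-8)

    def test_plug_in_statistic(self):
        est = smr(self.make(0.5, 0.05), self.make(0.1, 0.02))
        assert est.beta == pytest.approx(0.2)
        assert est.extra["t_smr"] == pytest.approx(20.0)
        assert est.se == pytest.approx(0.2 / np.sqrt(20.0))

    def test_infinite_eqtl_precision_limit(self):
        est = smr(self.make(0.5, 1e-9), self.make(0.1, 0.02))
        # T -> z_gwas^2; se -> first-order Wald-ratio se
        assert est.extra["t_smr"] == pytest.approx((0.1 / 0.02) ** 2, rel=1e-6)
        assert est.se == pytest.approx(0.02 / 0.5, rel=1e-6)

    def test_null_gwas(self):
        est = smr(self.make(0.5, 0.05), self.make(0.0, 0.02))
        assert est.beta == 0.0
        assert est.extra["t_smr"] == 0.0
        assert est.pval == 1.0

    def test_zero_eqtl_beta_raises(self):
        with pytest.raises(ZeroDivisionError):
            smr(self.make(0.0, 0.05), self.make(0.1, 0.02))


class TestScaleEquivariance:
    @pytest.mark.parametrize("k", [2.0, -0.5])
    def test_rescaling_exposure_divides_estimates(self, k):
        t = random_mr_table(np.random.default_rng(7), j=12)
        t2 = t.copy()
        t2["beta_exp"] = t2["beta_exp"] * k
        t2["se_exp"] = t2["se_exp"] * abs(k)
        assert ivw(t2).beta == pytest.approx(ivw(t).beta / k, rel=1e-10)
        assert mr_egger(t2).beta == pytest.approx(mr_egger(t).beta / k, rel=1e-10)
        wm1 = weighted_median(t, n_boot=10, seed=3).beta
        wm2 = weighted_median(t2, n_boot=10, seed=3).beta
        assert wm2 == pytest.approx(wm1 / k, rel=1e-10)
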