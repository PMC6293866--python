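"""Box-Cox lambda MLE, covariate adjustment and measurer averaging."""

import numpy as np
import pytest
from scipy import stats

from operadens.preprocess import (
    DensityStandardizer,
    PreprocessError,
    adjust_and_standardize,
    average_measurers,
    boxcox_lambda_mle,
    boxcox_transform,
)
from operadens.simulate import backtransform_to_raw


def _grid_oracle(y, lo=-3.0, hi=3.0, step=1e-3):
    grid = np.arange(lo, hi + step, step)
    lls = np.array([stats.boxcox_llf(l, y) for l in grid])
    return grid[int(np.argmax(lls))]


class TestBoxCoxLambda:
    @pytest.mark.parametrize("gen,lam_range", [
        (lambda rng: rng.lognormal(0.0, 1.0, 10_000), (-0.1, 0.1)),
        (lambda rng: rng.normal(50.0, 2.0, 10_000), (0.5, 1.5)),
    ])
    def test_recovers_generative_family(self, rng, gen, lam_range):
        y = gen(rng)
        fit = boxcox_lambda_mle(y)
        assert lam_range[0] < fit.lam < lam_range[1]
        # independent 0.001-step grid-search oracle
        assert fit.lam == pytest.approx(_grid_oracle(y), abs=2e-3)

    def test_roundtrip_through_inverse_transform(self, rng):
        # normal z pushed through the lambda=0.5 inverse map: the forward
        # MLE should recover lambda ~ 0.5
        z = rng.standard_normal(10_000)
        y = backtransform_to_raw(z, 0.5, 20.0, 4.0)
        fit = boxcox_lambda_mle(y)
        assert fit.lam == pytest.approx(0.5, abs=0.1)

    def test_nonpositive_without_shift_rejected(self):
        with pytest.raises(PreprocessError, match="shift"):
            boxcox_lambda_mle(np.array([0.0, 1.0, 2.0]))

    def test_shift_enables_fit(self):
        fit = boxcox_lambda_mle(np.array([0.0, 1.0, 2.0, 5.0]), shift=0.5)
        assert np.isfinite(fit.loglik)
        assert fit.shift == 0.5


class TestAdjustAndStandardize:
    def test_control_sd_is_exactly_one(self, rng):
        n = 400
        age = rng.normal(57, 7, n)
        bmi = rng.normal(26.5, 4.9, n)
        t = 0.02 * age + 0.03 * bmi + rng.normal(0, 0.5, n)
        ctl = rng.random(n) < 0.75
        adj = adjust_and_standardize(t, age, bmi, ctl)
        assert np.std(adj.values_standardized[ctl], ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert adj.sd_adjusted <= adj.sd_unadjusted + 1e-12

    def test_no_confounding_reduces_to_center_scale(self, rng):
        n = 500
        age, bmi = rng.normal(57, 7, n), rng.normal(26, 5, n)
        t = rng.normal(0, 0.6, n)
        adj = adjust_and_standardize(t, age, bmi, np.ones(n, bool))
        assert adj.sd_adjusted == pytest.approx(adj.sd_unadjusted, rel=0.02)
        expected = (t - t.mean()) / np.std(t - t.mean(), ddof=1)
        # chance covariate fit perturbs values by R^2 ~ 2/n only
        assert np.corrcoef(adj.values_standardized, expected)[0, 1] > 0.995

    def test_perfect_covariate_fit_rejected(self, rng):
        n = 100
        age = rng.normal(57, 7, n)
        bmi = rng.normal(26, 5, n)
        with pytest.raises(PreprocessError, match="zero adjusted SD"):
            adjust_and_standardize(0.05 * age, age, bmi, np.ones(n, bool))

    def test_collinear_covariates_rejected(self, rng):
        n = 100
        age = rng.normal(57, 7, n)
        t = rng.normal(0, 1, n)
        with pytest.raises(PreprocessError, match="rank"):
            adjust_and_standardize(t, age, 2.0 * age, np.ones(n, bool))

    def test_adjustment_shrinks_log_or_proportionally(self, rng):
        # strong age+BMI dependence: the per-unadjusted-SD log-OR exceeds
        # the per-adjusted-SD log-OR by exactly sd_unadjusted/sd_adjusted
        n = 1000
        age, bmi = rng.normal(57, 7, n), rng.normal(26.5, 4.9, n)
        t = 0.05 * age + 0.06 * bmi + rng.normal(0, 0.3, n)
        ctl = np.ones(n, bool)
        adj = adjust_and_standardize(t, age, bmi, ctl)
        ratio = adj.sd_adjusted / adj.sd_unadjusted
        assert ratio < 0.8
        beta_adj = 0.5  # log-odds per adjusted SD, by construction
        beta_unadj_sd = beta_adj * ratio  # same effect per unadjusted SD units
        assert beta_unadj_sd / beta_adj == pytest.approx(ratio)

    def test_idempotence(self, rng):
        n = 300
        age, bmi = rng.normal(57, 7, n), rng.normal(26, 5, n)
        t = 0.03 * age + rng.normal(0, 0.5, n)
        ctl = np.ones(n, bool)
        once = adjust_and_standardize(t, age, bmi, ctl)
        twice = adjust_and_standardize(once.values_standardized, age, bmi, ctl)
        np.testing.assert_allclose(twice.values_standardized,
                                   once.values_standardized, atol=1e-8)
        assert np.allclose(twice.coef[1:], 0.0, atol=1e-10)
        assert twice.sd_adjusted == pytest.approx(1.0, abs=1e-10)


class TestDensityStandardizer:
    def test_affine_invariance_of_standardized_values(self, rng):
        # rescaling raw y by a positive constant and re-estimating lambda
        # leaves the standardized output unchanged
        n = 800
        age, bmi = rng.normal(57, 7, n), rng.normal(26, 5, n)
        y = backtransform_to_raw(rng.standard_normal(n), 0.4, 18.0, 8.0)
        X1 = np.column_stack([y, age, bmi])
        X2 = np.column_stack([3.7 * y, age, bmi])
        s1 = DensityStandardizer().fit_transform(X1)
        s2 = DensityStandardizer().fit_transform(X2)
        np.testing.assert_allclose(s1, s2, atol=1e-4)

    def test_case_rows_use_control_coefficients(self, rng):
        n = 600
        age, bmi = rng.normal(57, 7, n), rng.normal(26, 5, n)
        y = backtransform_to_raw(rng.standard_normal(n) + 0.02 * (age - 57), 0.4, 18.0, 8.0)
        ctl = rng.random(n) < 0.7
        std = DensityStandardizer()
        std.fit(np.column_stack([y, age, bmi]), controls=ctl)
        vals = std.transform(np.column_stack([y, age, bmi]))
        assert np.std(vals[ctl], ddof=1) == pytest.approx(1.0, abs=1e-10)
        # case standardization must not depend on case values at all
        y2 = y.copy()
        y2[~ctl] *= 1.5
        std2 = DensityStandardizer()
        std2.fit(np.column_stack([y2, age, bmi]), controls=ctl)
        assert std2.lambda_ == pytest.approx(std.lambda_)
        np.testing.assert_allclose(std2.coef_, std.coef_)

    def test_auto_shift_applied_for_zeros(self, rng):
        y = np.r_[0.0, rng.lognormal(1.0, 0.5, 200)]
        age, bmi = rng.normal(57, 7, 201), rng.normal(26, 5, 201)
        std = DensityStandardizer()
        std.fit(np.column_stack([y, age, bmi]))
        assert std.shift_ > 0


class TestAverageMeasurers:
    def test_single_measurer_identity(self, rng):
        v = rng.standard_normal(50)
        avg, sd = average_measurers([v])
        np.testing.assert_allclose(avg, v)

    def test_perfectly_correlated_measurers(self, rng):
        v = rng.standard_normal(50)
        avg, _ = average_measurers([v, v.copy()])
        np.testing.assert_allclose(avg, v)

    def test_equicorrelated_five_measurers_sd(self, rng):
        # five unit-variance measurers with pairwise correlation 0.90:
        # SD of the mean = sqrt((1 + 4*0.90)/5) ~ 0.959
        n, k, r = 200_000, 5, 0.90
        common = rng.standard_normal(n)
        ms = [np.sqrt(r) * common + np.sqrt(1 - r) * rng.standard_normal(n)
              for _ in range(k)]
        _, sd = average_measurers(ms)
        assert sd == pytest.approx(np.sqrt((1 + (k - 1) * r) / k), abs=0.01)

    def test_mismatched_subjects_rejected(self, rng):
        with pytest.raises(PreprocessError, match="different subject sets"):
            average_measurers([rng.standard_normal(10), rng.standard_normal(11)])


def test_boxcox_transform_rejects_nonpositive():
    with pytest.raises(PreprocessError):
        boxcox_transform(np.array([-1.0, 2.0]), 0.5)
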