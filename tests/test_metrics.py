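"""OPERA, IQQR, BIC posterior odds, AUC, quartile ORs and ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from operadens.clogit import fit_clogit
from operadens.metrics import (
    MetricsError,
    auc_adjusted,
    bivariable_opera,
    delta_bic,
    icc,
    iqrr,
    opera_from_fit,
    quartile_ors,
)

from conftest import simulate_sets


class TestOperaFromFit:
    def test_null_fit_gives_unit_opera_and_iqrr(self, rng):
        fit = fit_clogit(*simulate_sets(rng, 400, 4, 0.0), terms=["x"])
        res = opera_from_fit(fit, "x")
        assert res.opera == pytest.approx(1.0, abs=0.12)
        assert iqrr(1.0) == 1.0

    @pytest.mark.parametrize("log_opera,printed", [(0.61, 1.84), (0.28, 1.32)])
    def test_exp_log_consistency_with_printed_values(self, log_opera, printed):
        assert np.exp(log_opera) == pytest.approx(printed, abs=0.005)

    def test_nonconverged_fit_refused(self, rng):
        fit = fit_clogit(*simulate_sets(rng, 50, 4, 0.0), terms=["x"])
        fit.converged = False
        with pytest.raises(MetricsError, match="converge"):
            opera_from_fit(fit, "x")


class TestBivariableOpera:
    def test_r_zero_identity(self, rng):
        X = rng.standard_normal((200 * 4, 2))
        _, y, groups = simulate_sets(rng, 200, 4, 0.0)
        fit = fit_clogit(X, y, groups, terms=["a", "b"])
        scaled = bivariable_opera(fit, ["a", "b"], 0.0)
        for t in ("a", "b"):
            assert scaled[t].log_opera == pytest.approx(
                fit.beta[fit.term_index(t)], abs=1e-12)

    def test_printed_scaling_arithmetic(self):
        # log OR 1 at r = 0.82: multiplier sqrt(1 - 0.6724) = 0.5724
        mult = np.sqrt(1 - 0.82 ** 2)
        assert mult == pytest.approx(0.5724, abs=5e-5)
        assert np.exp(1.0 * mult) == pytest.approx(1.772, abs=5e-4)

    def test_perfect_correlation_rejected(self, rng):
        fit = fit_clogit(*simulate_sets(rng, 30, 3, 0.2), terms=["a"])
        with pytest.raises(MetricsError, match="indistinguishable"):
            bivariable_opera(fit, ["a"], 1.0)

    def test_null_measure_collapses_in_joint_fit(self, rng):
        # two measures correlated 0.82, only the first causal
        n_sets, size = 400, 4
        n = n_sets * size
        r = 0.82
        x1 = rng.standard_normal(n)
        x2 = r * x1 + np.sqrt(1 - r * r) * rng.standard_normal(n)
        beta = 0.85
        _, y, groups = simulate_sets(rng, n_sets, size, beta, x=x1)
        fit = fit_clogit(np.column_stack([x1, x2]), y, groups, terms=["true", "null"])
        scaled = bivariable_opera(fit, ["true", "null"], r)
        assert scaled["true"].ci_low > 1.0
        assert scaled["null"].ci_low < 1.0 < scaled["null"].ci_high


class TestIqrr:
    def test_printed_interval_cancer_value(self):
        assert round(iqrr(2.33)) == 8  # "~ 8-fold"

    def test_printed_screen_value(self):
        assert iqrr(1.35) == pytest.approx(2.12, abs=0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(0.1, 10.0), y=st.floats(0.1, 10.0))
    def test_monotone_and_reciprocal(self, x, y):
        if x < y:
            assert iqrr(x) < iqrr(y)
        assert iqrr(1.0 / x) == pytest.approx(1.0 / iqrr(x), rel=1e-9)


class TestDeltaBic:
    def test_paper_posterior_odds_examples(self):
        # dBIC = -6 -> ~400; dBIC = -14 -> ~1,000,000 (1 s.f.)
        c6 = delta_bic(3.0, 0.0, 1, 1)  # 2*dLL = 6 in favour of A
        assert c6.delta_bic == pytest.approx(-6.0)
        assert round(c6.posterior_odds, -2) == 400
        c14 = delta_bic(7.0, 0.0, 1, 1)
        assert c14.delta_bic == pytest.approx(-14.0)
        exponent = np.floor(np.log10(c14.posterior_odds))
        one_sf = round(c14.posterior_odds / 10 ** exponent) * 10 ** exponent
        assert one_sf == 1_000_000

    def test_zero_difference(self):
        c = delta_bic(-10.0, -10.0, 2, 2)
        assert c.posterior_odds == 1.0
        assert c.verbal_strength == "none-existent"

    @pytest.mark.parametrize("dll,strength", [
        (0.5, "none-existent"), (2.0, "positive"), (4.0, "strong"), (6.0, "very strong")])
    def test_strength_bands(self, dll, strength):
        assert delta_bic(dll, 0.0, 1, 1).verbal_strength == strength

    def test_unequal_params_require_n(self):
        with pytest.raises(MetricsError, match="sample size"):
            delta_bic(-10.0, -12.0, 3, 2)
        c = delta_bic(-10.0, -12.0, 3, 2, n=100)
        assert c.delta_bic == pytest.approx(-4.0 + np.log(100))

    def test_halved_convention(self):
        c = delta_bic(3.0, 0.0, 1, 1, convention="halved")
        assert c.posterior_odds == pytest.approx(np.exp(3.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(dll=st.floats(-5, 5))
    def test_posterior_odds_reciprocal_symmetry(self, dll):
        a = delta_bic(dll, 0.0, 1, 1).posterior_odds
        b = delta_bic(0.0, dll, 1, 1).posterior_odds
        assert a * b == pytest.approx(1.0, rel=1e-9)


class TestAuc:
    def test_identical_distributions_half(self, rng):
        v = rng.standard_normal(4000)
        case = np.zeros(4000, bool)
        case[:2000] = True
        auc, (lo, hi) = auc_adjusted(v, case)
        assert auc == pytest.approx(0.5, abs=0.04)
        assert lo < 0.5 < hi

    def test_perfect_separation_one(self):
        v = np.r_[np.zeros(50), np.ones(50)]
        case = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        auc, _ = auc_adjusted(v, case)
        assert auc == 1.0

    def test_binormal_closed_form(self, rng):
        # unit-SD measure, case shift delta: AUC = Phi(delta / sqrt(2))
        delta = float(np.log(2.33))
        n = 30_000
        v = np.r_[rng.standard_normal(n) + delta, rng.standard_normal(3 * n)]
        case = np.r_[np.ones(n, bool), np.zeros(3 * n, bool)]
        auc, _ = auc_adjusted(v, case)
        expected = stats.norm.cdf(delta / np.sqrt(2))
        assert expected == pytest.approx(0.73, abs=0.005)
        assert auc == pytest.approx(expected, abs=0.01)

    def test_matches_sklearn_point_estimate(self, rng):
        from sklearn.metrics import roc_auc_score

        v = rng.standard_normal(500)
        case = rng.random(500) < 0.3
        auc, _ = auc_adjusted(v, case)
        assert auc == pytest.approx(roc_auc_score(case, v), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        v = rng.standard_normal(800)
        case = rng.random(800) < 0.4
        a1, _ = auc_adjusted(v, case)
        a2, _ = auc_adjusted(np.exp(2.0 * v) + 7, case)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(MetricsError):
            auc_adjusted(rng.standard_normal(10), np.ones(10, bool))


class TestQuartileOrs:
    def test_hand_made_controls_split_evenly(self):
        # 8 distinct control values split 2/2/2/2 by the 25/50/75 cuts
        v = np.arange(1.0, 9.0)
        cut = np.quantile(v, [0.25, 0.5, 0.75])
        q = np.digitize(v, cut)
        assert list(np.bincount(q)) == [2, 2, 2, 2]

    def test_null_data_unit_ors(self, rng):
        x, y, groups = simulate_sets(rng, 500, 4, 0.0)
        ors, fit, _ = quartile_ors(x, y, groups)
        for v in ors.values():
            assert 0.6 < v < 1.6

    def test_monotone_gradient_under_strong_effect(self, rng):
        x, y, groups = simulate_sets(rng, 600, 4, 0.85)
        ors, _, _ = quartile_ors(x, y, groups)
        assert ors["Q4"] > ors["Q3"] > ors["Q2"] > 1.0

    def test_tied_cutpoints_rejected(self, rng):
        v = np.r_[np.zeros(100), [1.0, 2.0, 3.0, 4.0, 5.0]]
        y = np.zeros(v.size, bool)
        with pytest.raises(MetricsError, match="collapse|quartile"):
            quartile_ors(v, y, np.arange(v.size))


class TestIcc:
    def test_exact_duplicates_give_one(self):
        groups = [np.array([1.3, 1.3]), np.array([-0.2, -0.2]), np.array([2.0, 2.0])]
        assert icc(groups).icc == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self, rng):
        pairs = rng.standard_normal((1000, 2))
        assert abs(icc(pairs).icc) < 0.05

    def test_ci_brackets_estimate(self, rng):
        pairs = np.array([[t + rng.normal(0, 0.2), t + rng.normal(0, 0.2)]
                          for t in rng.standard_normal(150)])
        res = icc(pairs)
        assert res.ci_low < res.icc < res.ci_high

    def test_matches_pingouin_reference(self, rng):
        import pandas as pd
        import pingouin as pg

        pairs = np.array([[t + rng.normal(0, 0.3), t + rng.normal(0, 0.3)]
                          for t in rng.standard_normal(60)])
        res = icc(pairs)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(60), 2),
            "raters": np.tile([0, 1], 60),
            "score": pairs.ravel()})
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        icc1 = float(ref["ICC"].iloc[0])  # first row is the one-way ICC(1,1)
        assert res.icc == pytest.approx(icc1, abs=1e-6)

    def test_all_singletons_rejected(self):
        with pytest.raises(MetricsError):
            icc([np.array([1.0]), np.array([2.0])])
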