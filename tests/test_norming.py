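"""Logistic age-of-attainment fits, the HL gate, spline refits and inversion."""

import numpy as np
import pytest
from scipy.special import expit, logit

from milenorm import norming
from milenorm.instrument import DAYS_PER_MONTH, ValidationError
from milenorm.norming import (
    LogisticItemModel,
    fit_item,
    fit_logistic,
    hosmer_lemeshow,
    milestone_months,
    percentile_age,
    rcs_basis,
    refit_spline,
)


def grid_search_mle(ages, y, alpha0, beta0, span=(2.0, 2.0), rounds=6, k=41):
    """Nested grid-search maximizer of the logistic log-likelihood."""
    best = (alpha0, beta0)
    sa, sb = span
    for _ in range(rounds):
        a_grid = np.linspace(best[0] - sa, best[0] + sa, k)
        b_grid = np.linspace(best[1] - sb, best[1] + sb, k)
        ll_best = -np.inf
        for a in a_grid:
            eta = a + np.outer(b_grid, ages)
            ll = (y * eta - np.logaddexp(0, eta)).sum(axis=1)
            j = int(np.argmax(ll))
            if ll[j] > ll_best:
                ll_best = ll[j]
                best = (a, b_grid[j])
        sa /= 8
        sb /= 8
    return best


class TestFitLogistic:
    def test_symmetric_data_puts_p50_at_center(self):
        m = fit_logistic(
            np.array([10.0, 20.0, 20.0, 30.0]), np.array([0.0, 0.0, 1.0, 1.0]),
            min_n=2,
        )
        assert m.model_form == "plain_logistic"
        assert percentile_age(m, 0.5) == pytest.approx(20.0, abs=1e-4)

    def test_all_pass_is_unfitted_all_pass_rendered_birth(self):
        m = fit_logistic(np.arange(30.0), np.ones(30))
        assert m.model_form == "unfitted_all_pass"
        assert all(v == 0.0 for v in milestone_months(m).values())

    def test_all_fail_is_degenerate(self):
        m = fit_logistic(np.arange(30.0), np.zeros(30))
        assert m.model_form == "unfitted_degenerate"
        assert np.isnan(percentile_age(m, 0.5))

    def test_below_min_n_is_degenerate(self):
        m = fit_logistic(np.arange(10.0), np.array([0, 1] * 5, dtype=float))
        assert m.model_form == "unfitted_degenerate"

    def test_matches_grid_search_oracle(self, rng):
        rng = np.random.default_rng(7)
        ages = rng.uniform(0, 100, 40)
        y = (rng.random(40) < expit(-3 + 0.06 * ages)).astype(float)
        m = fit_logistic(ages, y)
        a, b = grid_search_mle(ages, y, m.alpha, m.beta, span=(1.0, 0.05))
        assert m.alpha == pytest.approx(a, abs=1e-3)
        assert m.beta == pytest.approx(b, abs=1e-3)

    def test_complete_separation_flagged_with_boundary(self):
        ages = np.concatenate([np.arange(20.0), 100 + np.arange(20.0)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        m = fit_logistic(ages, y)
        assert m.separation
        assert m.separation_age == pytest.approx((19 + 100) / 2)
        for p in (0.25, 0.5, 0.9):
            assert percentile_age(m, p) == pytest.approx(m.separation_age)

    def test_negative_slope_gives_unattained_milestones(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(0, 100, 50)
        y = (rng.random(50) < expit(2 - 0.05 * ages)).astype(float)
        m = fit_logistic(ages, y)
        assert m.beta < 0
        assert np.isnan(percentile_age(m, 0.9))


class _StubModel(LogisticItemModel):
    """Fixed-probability model for hand-computed HL arithmetic."""

    def __init__(self, lo, hi):
        super().__init__(item_code="stub", model_form="plain_logistic",
                         alpha=0.0, beta=1.0, converged=True)
        self._lo, self._hi = lo, hi

    def predict(self, ages_days):
        a = np.asarray(ages_days, dtype=float)
        return np.where(a < 0, self._lo, self._hi)


class TestHosmerLemeshow:
    def test_two_group_toy_against_hand_arithmetic(self):
        # group A: 10 obs, p=0.4 (E=4), 3 observed; group B: 10 obs, p=0.6 (E=6), 7 observed
        ages = np.concatenate([-np.ones(10), np.ones(10)])
        y = np.concatenate([np.repeat([0.0, 1.0], [7, 3]), np.repeat([0.0, 1.0], [3, 7])])
        d = hosmer_lemeshow(_StubModel(0.4, 0.6), ages, y, groups=2)
        # (3-4)^2/(4*(1-0.4)) + (7-6)^2/(6*(1-0.6)) = 1/2.4 + 1/2.4
        assert d.hl_statistic == pytest.approx(2 / 2.4)

    def test_perfect_calibration_gives_zero_statistic(self):
        ages = np.concatenate([-np.ones(10), np.ones(10)])
        y = np.concatenate([np.repeat([0.0, 1.0], [6, 4]), np.repeat([0.0, 1.0], [4, 6])])
        d = hosmer_lemeshow(_StubModel(0.4, 0.6), ages, y, groups=2)
        assert d.hl_statistic == pytest.approx(0.0, abs=1e-12)
        assert d.hl_p == pytest.approx(1.0)

    def test_ten_groups_give_eight_df(self, rng):
        ages = rng.uniform(0, 1000, 300)
        y = (rng.random(300) < expit(-3 + 0.006 * ages)).astype(float)
        m = fit_logistic(ages, y)
        d = hosmer_lemeshow(m, ages, y, groups=10)
        assert d.hl_df == 8

    def test_tied_probabilities_merge_groups(self):
        ages = np.concatenate([-np.ones(20), np.ones(20)])
        y = np.concatenate([np.zeros(12), np.ones(8), np.zeros(8), np.ones(12)])
        d = hosmer_lemeshow(_StubModel(0.45, 0.55), ages, y, groups=10)
        assert d.hl_df == 1  # only 2 distinct risk values -> 2 groups, clamped df


class TestSplineRefit:
    def test_rcs_basis_linear_tails(self):
        knots = np.array([10.0, 30.0, 60.0, 90.0])
        x = np.array([-100.0, -50.0, 200.0, 250.0])
        B = rcs_basis(x, knots)
        # below the first knot every nonlinear term vanishes
        assert np.allclose(B[:2, 1:], 0.0)
        # beyond the last knot the curve is linear: second differences vanish
        x2 = np.array([200.0, 225.0, 250.0])
        B2 = rcs_basis(x2, knots)
        second_diff = B2[0] - 2 * B2[1] + B2[2]
        assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_nested_recovery_of_plain_logistic(self):
        rng = np.random.default_rng(21)
        ages = rng.uniform(0, 1500, 1200)
        y = (rng.random(1200) < expit(-4 + 0.005 * ages)).astype(float)
        plain = fit_logistic(ages, y)
        spline = refit_spline(ages, y)
        assert spline.converged
        for p in (0.25, 0.5, 0.9):
            a_plain = percentile_age(plain, p)
            a_spline = percentile_age(spline, p)
            assert a_spline == pytest.approx(a_plain, rel=0.06)

    def test_plateau_then_rise_rescued_by_spline(self):
        rng = np.random.default_rng(11)
        n = 1500
        ages = rng.uniform(0, 2000, n)
        p = np.where(ages < 900, 0.40, 0.40 + 0.60 * expit((ages - 1400) / 90))
        y = (rng.random(n) < p).astype(float)
        model, diag = fit_item(ages, y)
        assert diag.refit_triggered
        assert model.model_form == "spline_logistic"
        final = hosmer_lemeshow(model, ages, y)
        assert final.hl_p >= 0.05

    def test_too_few_observations_for_basis_rejected(self):
        with pytest.raises(ValidationError, match="identify"):
            refit_spline(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0.0, 1.0, 0.0, 1.0]),
                         knots=np.array([1.0, 1.5, 2.0, 3.0, 4.0]))


class TestPercentileAge:
    def test_closed_form_inversion_example(self):
        m = LogisticItemModel(item_code="x", model_form="plain_logistic",
                              alpha=-4.394, beta=0.02, converged=True)
        assert percentile_age(m, 0.9) == pytest.approx((logit(0.9) + 4.394) / 0.02)
        assert percentile_age(m, 0.9) == pytest.approx(329.6, abs=0.1)

    def test_clipped_at_birth(self):
        m = LogisticItemModel(item_code="x", model_form="plain_logistic",
                              alpha=2.0, beta=0.01, converged=True)
        assert percentile_age(m, 0.25) == 0.0

    def test_strictly_increasing_in_p(self):
        m = LogisticItemModel(item_code="x", model_form="plain_logistic",
                              alpha=-5.0, beta=0.01, converged=True)
        ps = np.linspace(0.05, 0.95, 19)
        ages = [percentile_age(m, p) for p in ps]
        assert all(b > a for a, b in zip(ages, ages[1:]))

    def test_equal_spacing_identity_for_plain_models(self):
        m = LogisticItemModel(item_code="x", model_form="plain_logistic",
                              alpha=-6.3, beta=0.007, converged=True)
        p25, p50, p75, p90 = (percentile_age(m, p) for p in (0.25, 0.5, 0.75, 0.9))
        assert p50 - p25 == pytest.approx(p75 - p50, abs=1e-9)
        assert p75 - p50 == pytest.approx(p90 - p75, abs=1e-9)

    def test_spline_inversion_matches_bisection_oracle(self):
        rng = np.random.default_rng(13)
        ages = rng.uniform(0, 1500, 1000)
        y = (rng.random(1000) < expit(-4 + 0.005 * ages)).astype(float)
        spline = refit_spline(ages, y)
        assert spline.converged
        for p in (0.25, 0.5, 0.75, 0.9):
            target = percentile_age(spline, p)
            lo, hi = 0.0, spline.age_range[1]
            for _ in range(60):  # plain bisection on the fitted curve
                mid = 0.5 * (lo + hi)
                if float(spline.predict(np.array([mid]))[0]) < p:
                    lo = mid
                else:
                    hi = mid
            assert target == pytest.approx(0.5 * (lo + hi), abs=0.01)

    def test_invalid_probability_rejected(self):
        m = LogisticItemModel(item_code="x", model_form="plain_logistic",
                              alpha=0.0, beta=0.01, converged=True)
        with pytest.raises(ValidationError):
            percentile_age(m, 1.0)


class TestParameterRecoveryScaling:
    def test_rmse_shrinks_with_sample_size(self):
        """RMSE of the P90 estimate shrinks roughly like 1/sqrt(n)."""
        rng = np.random.default_rng(17)
        truth_a, truth_b = -6.0, 0.008
        t90 = (logit(0.9) - truth_a) / truth_b
        rmse = {}
        for n in (200, 3200):
            errs = []
            for _ in range(40):
                ages = rng.uniform(0, 1800, n)
                y = (rng.random(n) < expit(truth_a + truth_b * ages)).astype(float)
                m = fit_logistic(ages, y)
                if m.model_form == "plain_logistic" and not m.separation:
                    errs.append(percentile_age(m, 0.9) - t90)
            rmse[n] = np.sqrt(np.mean(np.square(errs)))
        assert rmse[200] > 2.0 * rmse[3200]  # ideal factor 4
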