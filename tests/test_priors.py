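import numpy as np
import pytest

from grnfilter.filters import GaussianBelief, MeasurementModel, update_linear
from grnfilter.model import augmented_dim
from grnfilter.priors import (
    PenaltySpec,
    RangeConstraint,
    apply_range_constraints,
    bb_step,
    iterative_thresholding_update,
    map_cost,
    map_gradient,
    soft_threshold,
    truncated_normal_moments,
)


def make_problem(rng, make_psd, d, m):
    pred = GaussianBelief(rng.standard_normal(d), make_psd(d))
    model = MeasurementModel(B=rng.standard_normal((m, d)), R=make_psd(m))
    y = rng.standard_normal(m)
    return pred, model, y


class TestMapCost:
    def test_zero_at_consistent_point(self, rng, make_psd):
        pred, model, _ = make_problem(rng, make_psd, 5, 2)
        y = model.B @ pred.mean
        assert map_cost(pred.mean, y, pred, model) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_hand_case(self):
        pred = GaussianBelief(np.zeros(1), np.eye(1))
        model = MeasurementModel(B=np.eye(1), R=np.eye(1))
        y = np.array([2.0])
        # residuals at xbar = 1: (2-1)^2 / 1 + (1-0)^2 / 1 = 2
        assert map_cost(np.array([1.0]), y, pred, model) == pytest.approx(2.0)
        # gradient at xbar = 0: -2*(2) + 0
        assert map_gradient(np.zeros(1), y, pred, model)[0] == pytest.approx(-4.0)

    def test_minimized_at_kalman_mean(self, rng, make_psd):
        for _ in range(5):
            pred, model, y = make_problem(rng, make_psd, 5, 3)
            mean = update_linear(pred, y, model).filtered.mean
            g = map_gradient(mean, y, pred, model)
            assert np.linalg.norm(g) < 1e-8

    def test_gradient_matches_finite_differences(self, rng, make_psd):
        pred, model, y = make_problem(rng, make_psd, 4, 2)
        x = rng.standard_normal(4)
        g = map_gradient(x, y, pred, model)
        eps = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            fd = (map_cost(x + e, y, pred, model) - map_cost(x - e, y, pred, model)) / (
                2 * eps
            )
            assert g[j] == pytest.approx(fd, abs=1e-5)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "u,a,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)]
    )
    def test_values(self, u, a, expected):
        assert soft_threshold(np.array([u]), np.array([a]))[0] == expected

    def test_zero_threshold_is_identity(self, rng):
        u = rng.standard_normal(10)
        np.testing.assert_array_equal(soft_threshold(u, np.zeros(10)), u)

    def test_never_grows_magnitude(self, rng):
        u = rng.standard_normal(20)
        a = rng.uniform(0, 2, 20)
        assert np.all(np.abs(soft_threshold(u, a)) <= np.abs(u) + 1e-15)

    def test_rejects_negative_threshold(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(2), np.array([0.5, -0.1]))


class TestBBStep:
    def test_equal_vectors(self):
        s = np.array([1.0, 2.0])
        assert bb_step(s, s) == pytest.approx(1.0)

    def test_formula(self):
        assert bb_step(np.array([1.0, 0.0]), np.array([2.0, 0.0])) == pytest.approx(2.0)

    def test_degenerate_falls_back(self):
        assert bb_step(np.zeros(2), np.ones(2), fallback=7.0) == 7.0
        assert bb_step(np.array([1.0, 0]), np.array([-1.0, 0]), fallback=3.0) == 3.0


class TestIterativeThresholding:
    def test_zero_penalty_recovers_kalman_mean(self, rng, make_psd):
        for d in (4, 10):
            pred, model, y = make_problem(rng, make_psd, d, 3)
            pen = PenaltySpec(lam=np.zeros(d), mode="lasso", lambda_scalar=0.0)
            x = iterative_thresholding_update(pred, y, model, pen)
            ref = update_linear(pred, y, model).filtered.mean
            np.testing.assert_allclose(x, ref, atol=1e-6)

    def test_huge_penalty_zeroes_coefficient_block(self, rng, make_psd):
        n = 2
        d = augmented_dim(n)
        pred = GaussianBelief(rng.standard_normal(d), make_psd(d))
        model = MeasurementModel.expression_levels(n, 0.01 * np.eye(n))
        pen = PenaltySpec.lasso(n, 1e9)
        x = iterative_thresholding_update(pred, y=rng.standard_normal(n), model=model, penalty=pen)
        assert np.all(x[n : n + n * n] == 0.0)

    def test_matches_2d_grid_search(self, rng):
        # brute-force oracle on a 2-D decoupled problem
        pred = GaussianBelief(np.array([0.8, -1.1]), np.diag([0.5, 0.2]))
        model = MeasurementModel(B=np.eye(2), R=np.diag([0.3, 0.4]))
        y = np.array([1.5, -0.2])
        lam = np.array([1.0, 2.0])
        pen = PenaltySpec(lam=lam, mode="lasso", lambda_scalar=1.0)

        gx = np.linspace(-2, 2, 2001)
        X0, X1 = np.meshgrid(gx, gx, indexing="ij")
        J = (
            (y[0] - X0) ** 2 / 0.3
            + (y[1] - X1) ** 2 / 0.4
            + (X0 - 0.8) ** 2 / 0.5
            + (X1 + 1.1) ** 2 / 0.2
            + lam[0] * np.abs(X0)
            + lam[1] * np.abs(X1)
        )
        i, j = np.unravel_index(np.argmin(J), J.shape)
        x = iterative_thresholding_update(pred, y, model, pen)
        assert x[0] == pytest.approx(gx[i], abs=2e-3)
        assert x[1] == pytest.approx(gx[j], abs=2e-3)

    def test_penalized_objective_not_worse_than_kalman_mean(self, rng, make_psd):
        pred, model, y = make_problem(rng, make_psd, 6, 3)
        lam = np.abs(rng.standard_normal(6))
        pen = PenaltySpec(lam=lam, mode="lasso", lambda_scalar=1.0)
        x = iterative_thresholding_update(pred, y, model, pen)
        ref = update_linear(pred, y, model).filtered.mean

        def obj(z):
            return map_cost(z, y, pred, model) + lam @ np.abs(z)

        assert obj(x) <= obj(ref) + 1e-9

    def test_fixed_point_property(self, rng, make_psd):
        pred, model, y = make_problem(rng, make_psd, 5, 2)
        lam = np.full(5, 0.5)
        pen = PenaltySpec(lam=lam, mode="lasso", lambda_scalar=0.5)
        x = iterative_thresholding_update(pred, y, model, pen, eps=1e-12, max_iter=2000)
        for alpha in (500.0, 2000.0):
            g = map_gradient(x, y, pred, model)
            fp = soft_threshold(x - g / alpha, lam / alpha)
            np.testing.assert_allclose(fp, x, atol=1e-4)


class TestPenaltySpec:
    def test_lasso_layout(self):
        pen = PenaltySpec.lasso(3, 2.0)
        d = augmented_dim(3)
        assert pen.lam.shape == (d,)
        assert np.all(pen.lam[:3] == 0) and np.all(pen.lam[3 + 9 :] == 0)
        assert np.all(pen.lam[3 : 3 + 9] == 2.0)

    def test_indicator_penalizes_flagged_entries_only(self):
        from grnfilter.model import fixture_indicator

        pen = PenaltySpec.indicator(fixture_indicator(), 1.0)
        assert pen.mode == "indicator"
        assert np.count_nonzero(pen.lam) == 6

    def test_strength_weights(self):
        E = np.zeros((2, 2))
        E[0, 1] = 5.0
        pen = PenaltySpec.indicator(E, 2.0)
        assert pen.mode == "weighted-indicator"
        assert pen.lam[2 + 1] == 10.0  # component a_1_2


class TestTruncatedNormal:
    def test_no_truncation(self):
        m, v = truncated_normal_moments(-np.inf, np.inf)
        assert (m, v) == pytest.approx((0.0, 1.0))

    def test_symmetric_interval_has_zero_mean(self):
        m, v = truncated_normal_moments(-1.3, 1.3)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert 0 < v < 1

    def test_half_normal(self):
        m, v = truncated_normal_moments(0.0, np.inf)
        assert m == pytest.approx(np.sqrt(2 / np.pi), abs=1e-10)
        assert v == pytest.approx(1 - 2 / np.pi, abs=1e-10)

    def test_rejects_bad_intervals(self):
        with pytest.raises(ValueError):
            truncated_normal_moments(1.0, 1.0)
        with pytest.raises(ValueError):
            truncated_normal_moments(50.0, 60.0)


class TestRangeConstraints:
    def test_infinite_bounds_identity(self, rng, make_psd):
        d = 5
        belief = GaussianBelief(rng.standard_normal(d), make_psd(d))
        rc = RangeConstraint(lower=np.full(d, -np.inf), upper=np.full(d, np.inf))
        out = apply_range_constraints(belief, rc)
        np.testing.assert_allclose(out.mean, belief.mean, atol=1e-10)
        np.testing.assert_allclose(out.cov, belief.cov, atol=1e-10)

    def test_scalar_half_line(self):
        belief = GaussianBelief(np.zeros(1), np.eye(1))
        rc = RangeConstraint(lower=np.array([0.0]), upper=np.array([np.inf]))
        out = apply_range_constraints(belief, rc)
        assert out.mean[0] == pytest.approx(np.sqrt(2 / np.pi), abs=1e-8)
        assert out.cov[0, 0] == pytest.approx(1 - 2 / np.pi, abs=1e-8)

    def test_matches_rank_one_closed_form(self, rng, make_psd):
        # independent oracle: truncating component i of N(m, P) to [lo, hi]
        # shifts the mean by mu_t * P[:, i] / sqrt(P_ii) and adds
        # (sigma_t^2 - 1) outer(P[:, i]) / P_ii to the covariance
        d = 4
        mean = rng.standard_normal(d)
        P = make_psd(d)
        i, lo, hi = 2, -0.5, 0.8
        sd = np.sqrt(P[i, i])
        mu_t, var_t = truncated_normal_moments((lo - mean[i]) / sd, (hi - mean[i]) / sd)
        want_mean = mean + mu_t * P[:, i] / sd
        want_cov = P + (var_t - 1.0) * np.outer(P[:, i], P[:, i]) / P[i, i]

        lower = np.full(d, -np.inf)
        upper = np.full(d, np.inf)
        lower[i], upper[i] = lo, hi
        out = apply_range_constraints(
            GaussianBelief(mean, P), RangeConstraint(lower=lower, upper=upper)
        )
        np.testing.assert_allclose(out.mean, want_mean, atol=1e-8)
        np.testing.assert_allclose(out.cov, want_cov, atol=1e-8)

    def test_mean_respects_bounds(self, rng, make_psd):
        d = 6
        for _ in range(5):
            belief = GaussianBelief(2 * rng.standard_normal(d), make_psd(d))
            lower = belief.mean - rng.uniform(0.1, 2.0, d)
            upper = belief.mean + rng.uniform(0.1, 2.0, d)
            out = apply_range_constraints(
                belief, RangeConstraint(lower=lower, upper=upper)
            )
            assert np.all(out.mean >= lower - 1e-8)
            assert np.all(out.mean <= upper + 1e-8)

    def test_truncated_direction_variance_never_grows(self, rng, make_psd):
        d = 4
        belief = GaussianBelief(rng.standard_normal(d), make_psd(d))
        lower = np.full(d, -np.inf)
        upper = np.full(d, np.inf)
        lower[1], upper[1] = -0.2, 0.4
        out = apply_range_constraints(belief, RangeConstraint(lower=lower, upper=upper))
        assert out.cov[1, 1] <= belief.cov[1, 1] + 1e-10

    def test_wide_bounds_idempotent(self, rng, make_psd):
        d = 3
        belief = GaussianBelief(rng.standard_normal(d), 0.01 * make_psd(d))
        rc = RangeConstraint(lower=np.full(d, -50.0), upper=np.full(d, 50.0))
        once = apply_range_constraints(belief, rc)
        twice = apply_range_constraints(once, rc)
        np.testing.assert_allclose(once.mean, twice.mean, atol=1e-8)
        np.testing.assert_allclose(once.cov, twice.cov, atol=1e-8)

    def test_rejects_crossed_bounds(self):
        with pytest.raises(ValueError):
            RangeConstraint(lower=np.array([1.0]), upper=np.array([0.0]))
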