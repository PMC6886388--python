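"""Core target-approximation dynamics: coefficients, evaluation, state transfer."""

import math

import numpy as np
import pytest
from scipy.special import gammaincc

from targetapprox import (
    BoundaryState,
    ConfigurationError,
    ModelConfig,
    TargetSpec,
    simulate_sequence,
    ta_coefficients,
    ta_derivative,
    ta_evaluate,
)


def rest(y0, order):
    return BoundaryState.at_rest(y0, order)


class TestCoefficients:
    def test_equilibrium_start_gives_zero_coefficients(self):
        c = ta_coefficients(rest(100.0, 4), TargetSpec(0, 100.0, 0.1), 20.0, 4)
        assert np.allclose(c.c, 0.0)

    def test_c0_is_initial_distance_from_target(self):
        c = ta_coefficients(rest(85.0, 3), TargetSpec(0, 100.0, 0.1), 20.0, 3)
        assert c.c[0] == pytest.approx(-15.0)

    def test_third_order_matches_published_qta_forms(self):
        rng = np.random.default_rng(7)
        lam = 20.0
        state = BoundaryState(rng.normal(0, 50, 3))
        tgt = TargetSpec(m=3.0, b=90.0, d=0.1)
        c = ta_coefficients(state, tgt, lam, 3)
        y0, v0, a0 = state.derivs
        c0 = y0 - tgt.b
        c1 = v0 + c0 * lam - tgt.m
        c2 = (a0 + 2 * c1 * lam - c0 * lam**2) / 2
        assert np.allclose(c.c, [c0, c1, c2], rtol=1e-12)

    @pytest.mark.parametrize("order", [1, 2, 3, 5, 8, 14])
    def test_matches_brute_force_linear_solve(self, order):
        """Coefficients solve the initial-condition system of the closed form.

        Independent oracle: build the linear system that matches y and its
        derivatives at t = 0 symbolically (d^k/dt^k [t^i e^{-lam t}] at 0
        equals k!/(k-i)! (-lam)^{k-i}) and solve it with a generic solver.
        """
        rng = np.random.default_rng(order)
        lam = 20.0
        state = BoundaryState(rng.normal(0, 30, order))
        tgt = TargetSpec(m=rng.normal(), b=95.0, d=0.1)
        A = np.zeros((order, order))
        for k in range(order):
            for i in range(k + 1):
                A[k, i] = math.factorial(k) / math.factorial(k - i) * (-lam) ** (k - i)
        rhs = state.derivs.copy()
        rhs[0] -= tgt.b
        if order > 1:
            rhs[1] -= tgt.m
        expected = np.linalg.solve(A, rhs)
        c = ta_coefficients(state, tgt, lam, order)
        # the triangular oracle system spans ~14 orders of magnitude at high
        # order, so the generic solve itself is only good to ~1e-8 relative
        assert np.allclose(c.c, expected, rtol=1e-6, atol=1e-9)

    def test_mismatched_state_length_raises(self):
        with pytest.raises(ConfigurationError):
            ta_coefficients(rest(85.0, 2), TargetSpec(0, 100, 0.1), 20.0, 3)

    def test_nonpositive_lambda_raises(self):
        with pytest.raises(ConfigurationError):
            ta_coefficients(rest(85.0, 2), TargetSpec(0, 100, 0.1), -5.0, 2)


class TestEvaluate:
    def test_zero_coefficients_stay_at_static_target(self):
        tgt = TargetSpec(0, 100.0, 0.5)
        c = ta_coefficients(rest(100.0, 4), tgt, 30.0, 4)
        t = np.linspace(0, 0.5, 100)
        assert np.allclose(ta_evaluate(c, tgt, 30.0, t), 100.0)

    def test_second_order_rest_start_closed_form_value(self):
        # y(t) = 100 - 15 e^{-20 t} (1 + 20 t); frozen at t = 0.1
        tgt = TargetSpec(0, 100.0, 0.2)
        c = ta_coefficients(rest(85.0, 2), tgt, 20.0, 2)
        y = ta_evaluate(c, tgt, 20.0, [0.1])
        assert y[0] == pytest.approx(93.90991225435243, abs=1e-9)

    def test_simple_movement_rises_monotonically_with_s_shaped_onset(self):
        tgt = TargetSpec(0, 100.0, 0.6)
        lam, order = 20.0, 3
        c = ta_coefficients(rest(80.0, order), tgt, lam, order)
        t = np.arange(0, 0.6, 1e-3)
        y = ta_evaluate(c, tgt, lam, t)
        assert np.all(np.diff(y) >= -1e-12)
        v = ta_derivative(c, tgt, lam, t, k=1)
        # unimodal velocity: slow start, peak, slow approach
        peak = np.argmax(v)
        assert 0 < peak < len(v) - 1
        assert v[0] < v[peak] / 10

    def test_empty_time_vector_gives_empty_result(self):
        tgt = TargetSpec(0, 100.0, 0.1)
        c = ta_coefficients(rest(85.0, 2), tgt, 20.0, 2)
        assert ta_evaluate(c, tgt, 20.0, []).size == 0


class TestDerivative:
    def test_constant_trajectory_has_zero_derivative(self):
        tgt = TargetSpec(0, 100.0, 0.1)
        c = ta_coefficients(rest(100.0, 3), tgt, 20.0, 3)
        t = np.linspace(0, 0.3, 50)
        for k in (1, 2, 3):
            assert np.allclose(ta_derivative(c, tgt, 20.0, t, k=k), 0.0)

    def test_rest_start_second_order_velocity_peak(self):
        # v(t) = 15 lam^2 t e^{-lam t}: peak 15 lam / e at t = 1/lam
        lam = 20.0
        tgt = TargetSpec(0, 100.0, 0.2)
        c = ta_coefficients(rest(85.0, 2), tgt, lam, 2)
        vpeak = ta_derivative(c, tgt, lam, [1 / lam], k=1)[0]
        assert vpeak == pytest.approx(15 * lam / np.e, rel=1e-12)
        t = np.arange(0, 0.3, 1e-4)
        v = ta_derivative(c, tgt, lam, t, k=1)
        assert abs(t[np.argmax(v)] - 1 / lam) < 2e-4

    @pytest.mark.parametrize("order,lam,m", [(2, 20.0, 0.0), (5, 65.0, 0.0), (8, 40.0, 12.0)])
    def test_first_derivative_matches_finite_difference(self, order, lam, m):
        rng = np.random.default_rng(order)
        state = BoundaryState(rng.normal(0, 20, order))
        tgt = TargetSpec(m, 90.0, 0.1)
        c = ta_coefficients(state, tgt, lam, order)
        t = np.linspace(0.01, 0.2, 25)
        h = 1e-6
        fd = (ta_evaluate(c, tgt, lam, t + h) - ta_evaluate(c, tgt, lam, t - h)) / (2 * h)
        v = ta_derivative(c, tgt, lam, t, k=1)
        assert np.allclose(v, fd, rtol=1e-4, atol=1e-4)

    def test_unsupported_derivative_order_raises(self):
        tgt = TargetSpec(0, 100.0, 0.1)
        c = ta_coefficients(rest(85.0, 2), tgt, 20.0, 2)
        with pytest.raises(ConfigurationError):
            ta_derivative(c, tgt, 20.0, [0.1], k=33)


class TestClosedFormProperties:
    @pytest.mark.parametrize("order", range(1, 11))
    @pytest.mark.parametrize("lam", [10.0, 65.0])
    def test_rest_start_equals_incomplete_gamma_form(self, order, lam):
        """|y(t) - b| = |y0 - b| Q(N, lam t) for rest starts at static targets."""
        tgt = TargetSpec(0, 100.0, 0.5)
        c = ta_coefficients(rest(85.0, order), tgt, lam, order)
        t = np.linspace(0, 0.5, 200)
        y = ta_evaluate(c, tgt, lam, t)
        expected = 100.0 - 15.0 * gammaincc(order, lam * t)
        assert np.allclose(y, expected, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("order", [1, 2, 3, 6, 10, 14])
    def test_ode_residual_is_zero(self, order):
        """(d/dt + lam)^N applied to (y - x) vanishes identically."""
        rng = np.random.default_rng(order)
        lam = 30.0
        state = BoundaryState(rng.normal(0, 20, order))
        tgt = TargetSpec(2.0, 90.0, 0.1)
        c = ta_coefficients(state, tgt, lam, order)
        t = np.linspace(0.0, 0.2, 50)
        # y - x has derivatives d^k = ta_derivative - x^(k)
        terms = []
        scale = 0.0
        for k in range(order + 1):
            if k == 0:
                dk = ta_evaluate(c, tgt, lam, t) - (tgt.m * t + tgt.b)
            else:
                dk = ta_derivative(c, tgt, lam, t, k=k).copy()
                if k == 1:
                    dk -= tgt.m
            coef = math.comb(order, k) * lam ** (order - k)
            terms.append(coef * dk)
            scale = max(scale, np.max(np.abs(coef * dk)))
        residual = np.sum(terms, axis=0)
        assert np.max(np.abs(residual)) <= 1e-6 * scale

    def test_linearity_scaling_of_rest_start(self):
        """Scaling (y0 - b) scales y - b and its derivatives exactly."""
        lam, order, s = 25.0, 6, 3.5
        tgt = TargetSpec(0, 100.0, 0.2)
        c1 = ta_coefficients(rest(95.0, order), tgt, lam, order)
        c2 = ta_coefficients(rest(100 + (95 - 100) * s, order), tgt, lam, order)
        t = np.linspace(0, 0.3, 40)
        y1 = ta_evaluate(c1, tgt, lam, t) - 100.0
        y2 = ta_evaluate(c2, tgt, lam, t) - 100.0
        assert np.allclose(y2, s * y1, rtol=1e-12)
        v1 = ta_derivative(c1, tgt, lam, t, k=1)
        v2 = ta_derivative(c2, tgt, lam, t, k=1)
        assert np.allclose(v2, s * v1, rtol=1e-12)


class TestSimulateSequence:
    def test_targets_at_initial_displacement_stay_flat(self):
        cfg = ModelConfig(order=4, lam=30.0, dt=0.001)
        targets = [TargetSpec(0, 85.0, d) for d in (0.1, 0.15, 0.1)]
        traj = simulate_sequence(targets, cfg, rest(85.0, 4))
        assert np.allclose(traj.y, 85.0)
        assert np.allclose(traj.v, 0.0)

    @pytest.mark.parametrize("order", [2, 4, 10])
    def test_junction_smoothness_of_transferred_state(self, order):
        """Derivatives 0..N-1 are continuous across boundaries; the N-th is not."""
        lam = 40.0
        targets = [TargetSpec(0, b, d) for b, d in ((80, 0.1), (100, 0.08), (80, 0.15))]
        state = rest(85.0, order)
        prev_end = None
        for tgt in targets:
            c = ta_coefficients(state, tgt, lam, order)
            derivs_start = [ta_evaluate(c, tgt, lam, [0.0])[0]] + [
                ta_derivative(c, tgt, lam, [0.0], k=k)[0] for k in range(1, order + 1)
            ]
            if prev_end is not None:
                for k in range(order):
                    assert derivs_start[k] == pytest.approx(
                        prev_end[k], rel=1e-6, abs=1e-6
                    ), f"derivative {k} discontinuous"
                # the N-th derivative jumps when the target changes
                assert abs(derivs_start[order] - prev_end[order]) > 1e-3
            d = tgt.d
            prev_end = [ta_evaluate(c, tgt, lam, [d])[0]] + [
                ta_derivative(c, tgt, lam, [d], k=k)[0] for k in range(1, order + 1)
            ]
            state = BoundaryState(np.asarray(prev_end[:order]))

    def test_sampled_trajectory_is_continuous_at_boundaries(self):
        cfg = ModelConfig(order=10, lam=85.0, dt=1e-4)
        targets = [TargetSpec(0, b, d) for b, d in ((80, 0.2), (100, 0.1), (80, 0.3))]
        traj = simulate_sequence(targets, cfg, rest(85.0, 10))
        # no sample-to-sample jump can exceed |v| dt by much
        jump = np.abs(np.diff(traj.y))
        bound = (np.abs(traj.v[:-1]) + np.abs(traj.v[1:])) * cfg.dt + 1e-6
        assert np.all(jump <= bound)

    def test_static_target_converges_when_held_long_enough(self):
        cfg = ModelConfig(order=3, lam=40.0, dt=0.001)
        traj = simulate_sequence([TargetSpec(0, 100.0, 0.5)], cfg, rest(85.0, 3))
        assert abs(traj.y[-1] - 100.0) < 1e-3

    def test_velocity_transfer_extends_third_movement_amplitude(self):
        """Carrying velocity across boundaries delays the turning point into
        the third movement and enlarges its amplitude, relative to resetting
        velocity to zero at each boundary."""
        order, lam = 2, 20.0
        cfg = ModelConfig(order=order, lam=lam, dt=0.001)
        targets = [TargetSpec(0, b, d) for b, d in ((80, 0.15), (100, 0.075), (80, 0.15))]

        transfer = simulate_sequence(targets, cfg, rest(85.0, order))

        # reset variant: each movement starts from rest at the carried displacement
        state = rest(85.0, order)
        segs = []
        for tgt in targets:
            seg = simulate_sequence([tgt], cfg, state)
            segs.append(seg)
            state = rest(seg.y[-1], order)
        y_reset = np.concatenate([segs[0].y] + [s.y[1:] for s in segs[1:]])

        def third_movement_amplitude(y):
            i_max = np.argmax(y)
            return y[i_max] - np.min(y[i_max:])

        assert third_movement_amplitude(transfer.y) > third_movement_amplitude(y_reset)

    def test_velocity_peak_moves_later_and_more_symmetric_with_order(self):
        """Higher order: middle-target velocity peak occurs later in its
        interval and the velocity profile becomes more symmetrical."""
        lam = 40.0
        targets = [TargetSpec(0, b, d) for b, d in ((80, 0.2), (100, 0.1), (80, 0.3))]
        rel_peak_pos, asym = [], []
        for order in (2, 8, 14):
            cfg = ModelConfig(order=order, lam=lam, dt=0.001)
            traj = simulate_sequence(targets, cfg, rest(85.0, order))
            v = traj.v
            # positive velocity episode belonging to the rise toward 100
            pos = np.where(v > 1e-6)[0]
            i0, i1 = pos[0], pos[-1]
            peak = i0 + np.argmax(v[i0 : i1 + 1])
            rel_peak_pos.append((traj.t[peak] - traj.t[i0]))
            rise, fall = peak - i0, i1 - peak
            asym.append(abs(rise - fall) / (rise + fall))
        assert rel_peak_pos == sorted(rel_peak_pos)
        assert asym[0] > asym[-1]

    def test_boundary_snap_is_recorded(self):
        cfg = ModelConfig(order=2, lam=20.0, dt=0.001)
        traj = simulate_sequence([TargetSpec(0, 90.0, 0.1004)], cfg, rest(85.0, 2))
        assert traj.meta.get("boundaries_snapped_to_grid") is True
        assert traj.boundaries[-1] == pytest.approx(0.100)

    def test_empty_target_list_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_sequence([], ModelConfig(order=2, lam=20.0), rest(85.0, 2))
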