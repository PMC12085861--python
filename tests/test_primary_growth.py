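"""Tropism strain seeding and the apical small-deflection system."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cocorod import MaterialFrame, apical_step, dms_curvature_rate, \
    env_adjusted_direction, tropism_strains
from cocorod.primary_growth import ApicalState, TropismTargets, \
    taylor_truncation_residual

from conftest import random_rotation_matrices, random_unit_vectors

EZ = np.array([0.0, 0.0, 1.0])
EX = np.array([1.0, 0.0, 0.0])


class TestEnvAdjustedDirection:
    def test_zero_angle_identity(self):
        f_star = np.array([0.1, 0.0, 1.0]) / np.linalg.norm([0.1, 0.0, 1.0])
        np.testing.assert_allclose(env_adjusted_direction(EZ, f_star, 0.0),
                                   EZ, atol=1e-14)

    def test_unit_norm_and_orthogonality(self, rng):
        f_star = np.array([0.1, 0.0, 1.0]) / np.linalg.norm([0.1, 0.0, 1.0])
        for theta in rng.uniform(-np.pi, np.pi, 20):
            out = env_adjusted_direction(EZ, f_star, theta)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
        tt = TropismTargets(f_p=EZ, f_p_star=f_star, theta=0.3)
        assert abs(tt.f_p_gamma @ tt.f_p_star) < 1e-12
        assert abs(tt.f_p_beta @ tt.f_p_gamma) < 1e-12

    def test_parallel_directions_degenerate(self):
        with pytest.raises(ValueError):
            env_adjusted_direction(EZ, EZ, 0.3)

    def test_strict_literal_mode_vanishes_at_key_angles(self):
        f_star = np.array([0.1, 0.0, 1.0]) / np.linalg.norm([0.1, 0.0, 1.0])
        for theta in (0.0, np.pi / 2):
            out = env_adjusted_direction(EZ, f_star, theta,
                                         strict_literal=True)
            assert np.linalg.norm(out) < 1e-12


class TestTropismStrains:
    def test_aligned_target_gives_zero_strains(self):
        frame = MaterialFrame.identity()
        assert tropism_strains(frame.f3, frame, 2.0) == (0.0, 0.0, 0.0)

    def test_printed_zero_beta_max_forces_straight_growth(self, rng):
        # the published parameter set uses beta_max = 0: no curvature at all
        frame = MaterialFrame.identity()
        for v in random_unit_vectors(rng, 20):
            assert tropism_strains(v, frame, 0.0) == (0.0, 0.0, 0.0)

    def test_perpendicular_target_closed_form(self):
        frame = MaterialFrame.identity()
        beta_max = 1.7
        beta0, dbeta0, gamma0 = tropism_strains(frame.f1, frame, beta_max)
        assert beta0 == pytest.approx(beta_max / math.sqrt(2), abs=1e-14)
        assert dbeta0 == pytest.approx(
            0.5 * beta_max**2 * (1 - math.sqrt(2)), abs=1e-12)
        assert gamma0 == 0.0

    def test_projection_system_solved_exactly_at_saturating_curvature(
            self, rng):
        # with beta_max = 2/delta the seeds solve the projected quadratic
        # Taylor system exactly: residuals vanish to machine precision
        delta = 0.1
        frame = MaterialFrame.identity()
        for v in random_unit_vectors(rng, 50):
            b0, db0, g0 = tropism_strains(v, frame, 2.0 / delta, delta)
            c1, c2, c3 = v  # identity frame: components are projections
            r1 = c1 - (b0 * delta + db0 * delta**2 / 2)
            r2 = c2 - b0 * g0 * delta**2 / 2
            r3 = c3 - (1 - b0**2 * delta**2 / 2)
            assert max(abs(r1), abs(r2), abs(r3)) < 1e-12

    def test_truncation_residual_second_order(self, rng):
        # substituting the seeds back into the rod kinematics reproduces
        # the quadratic construction with empirical order >= 2 in delta
        n = 100
        targets = random_unit_vectors(rng, n)
        frames = random_rotation_matrices(rng, n)
        med = {d: float(np.median(taylor_truncation_residual(
            targets, frames, 0.5, d))) for d in (0.1, 0.05, 0.025)}
        assert math.log2(med[0.1] / med[0.05]) >= 2.0
        assert math.log2(med[0.05] / med[0.025]) >= 2.0

    def test_sqrt_clamped_against_rounding(self):
        frame = MaterialFrame.identity()
        target = np.array([0.0, 0.0, 1.0 + 5e-9])  # unit within tolerance
        b0, db0, g0 = tropism_strains(target, frame, 1.0)
        assert np.isfinite([b0, db0, g0]).all()

    def test_rejects_non_unit_target(self):
        with pytest.raises(ValueError):
            tropism_strains(np.array([0.0, 0.0, 2.0]),
                            MaterialFrame.identity(), 1.0)


class TestDmsCurvatureRate:
    def test_zero_misalignment(self):
        assert dms_curvature_rate(0.01, 0.01, 0.001, 0.5, 0.5) == 0.0

    def test_printed_parameter_evaluation(self):
        # v_gamma = V^r = 0.01 m/y, s = 0.01 m, alpha = 0.001,
        # theta_p_f = 0.61*pi, theta = 0
        p = dms_curvature_rate(0.01, 0.01, 0.001, 0.61 * math.pi, 0.0)
        expected = 2.0 * 0.01 / 0.01**2 * 0.001 * math.sin(0.61 * math.pi)
        assert p == pytest.approx(expected, rel=1e-14)

    @given(st.floats(-3.0, 3.0), st.floats(-3.0, 3.0))
    def test_antisymmetry_in_misalignment(self, a, b):
        p1 = dms_curvature_rate(0.01, 0.01, 0.001, a, b)
        p2 = dms_curvature_rate(0.01, 0.01, 0.001, b, a)
        assert p1 == pytest.approx(-p2, abs=1e-15)

    def test_rejects_non_positive_scale(self):
        with pytest.raises(ValueError):
            dms_curvature_rate(0.01, 0.0, 0.001, 0.5, 0.1)


class TestApicalStep:
    def test_unloaded_straight_rod_is_fixed_point(self):
        r = np.linspace(0.0, 5.0, 501)
        state = ApicalState.initial(r, theta_0=0.0, beta_star_init=0.0)
        out = apical_step(state, rigidity=1e6, dt=0.05)
        np.testing.assert_array_equal(out.q, np.zeros_like(r))
        np.testing.assert_array_equal(out.theta, np.zeros_like(r))
        np.testing.assert_allclose(out.s[:, 0], r, atol=1e-12)
        np.testing.assert_array_equal(out.s[:, 1], np.zeros_like(r))

    def test_constant_load_couple_matches_hand_integral(self):
        # theta ~ 0: dq/dr = -p_y with q(k) = 0 gives q(r) = p_y (k - r)
        r = np.linspace(0.0, 4.0, 401)
        state = ApicalState.initial(r, theta_0=0.0, beta_star_init=0.0)
        p_y = 2.5
        out = apical_step(state, rigidity=1e9, dt=0.05, p_y=p_y)
        np.testing.assert_allclose(out.q, p_y * (r[-1] - r), rtol=1e-12)

    def test_tip_condition_and_base_clamps_hold_every_step(self):
        r = np.linspace(0.0, 3.0, 301)
        state = ApicalState.initial(r, theta_0=0.1, beta_star_init=0.02)
        for _ in range(10):
            state = apical_step(state, rigidity=5e5, dt=0.05, p_y=1.0,
                                rigidity_rate=1e3)
            assert state.q[-1] == 0.0
            assert state.theta[0] == pytest.approx(0.1, abs=1e-15)
            np.testing.assert_array_equal(state.s[0], [0.0, 0.0])

    def test_rejects_non_positive_rigidity(self):
        r = np.linspace(0.0, 1.0, 11)
        state = ApicalState.initial(r, 0.0, 0.0)
        with pytest.raises(ValueError):
            apical_step(state, rigidity=0.0, dt=0.05)
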