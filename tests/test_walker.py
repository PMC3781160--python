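"""Walker dynamics: torque law, collision, phase ODEs, step integration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stridewalk as sw
from stridewalk.walker import (dpsi_dtheta, d2psi_dtheta2, psi_of_theta,
                               theta_of_psi)

from helpers import dae_hip_trajectory, quad_step_durations, thetadot_sq

PI12 = math.pi / 12
PI6 = math.pi / 6


@pytest.fixture(scope="module")
def p12():
    return sw.WalkerParams(theta0=PI12, k0=86.54)


@pytest.fixture(scope="module")
def p6():
    return sw.WalkerParams(theta0=PI6, k0=1028.8)


# ---------------------------------------------------------------------------
# ankle torque (linear spring released at double-stance onset)
# ---------------------------------------------------------------------------

class TestAnkleTorque:
    def test_zero_at_full_plantar_flexion(self, p12):
        # release point of the spring: torque vanishes exactly at psi = mu
        assert sw.ankle_torque(p12.mu, 123.4, p12) == 0.0

    def test_zero_stiffness(self, p12):
        assert sw.ankle_torque(1.0, 0.0, p12) == 0.0

    @given(psi1=st.floats(0.1, 2.5), psi2=st.floats(0.1, 2.5),
           k=st.floats(1.0, 500.0))
    def test_linearity(self, psi1, psi2, k):
        p = sw.WalkerParams(theta0=PI12, k0=100.0)
        t1 = sw.ankle_torque(psi1, k, p)
        t2 = sw.ankle_torque(psi2, k, p)
        assert t1 - t2 == pytest.approx(k * (psi2 - psi1), rel=1e-12, abs=1e-12)

    def test_positive_before_release(self, p12):
        assert sw.ankle_torque(p12.psi0, 50.0, p12) > 0

    def test_phase_violation_beyond_mu(self, p12):
        with pytest.raises(sw.PhaseViolationError):
            sw.ankle_torque(p12.mu + 0.01, 50.0, p12)


# ---------------------------------------------------------------------------
# heel-strike collision
# ---------------------------------------------------------------------------

class TestCollision:
    @pytest.mark.parametrize("theta0, expected", [
        (PI6, 0.5),            # cos(pi/3)
        (PI12, math.sqrt(3) / 2),  # cos(pi/6)
    ])
    def test_reduction_factor(self, theta0, expected):
        p = sw.WalkerParams(theta0=theta0, k0=100.0)
        assert sw.collision_map(1.0, p) == pytest.approx(expected, abs=1e-12)

    def test_identity_limit_small_theta0(self):
        p = sw.WalkerParams(theta0=1e-9, k0=100.0)
        assert sw.collision_map(1.0, p) == pytest.approx(1.0, abs=1e-12)

    @given(theta0=st.floats(0.01, math.pi / 4 - 0.01),
           omega=st.floats(1e-6, 10.0))
    def test_speed_ratio_and_energy_ratio(self, theta0, omega):
        p = sw.WalkerParams(theta0=theta0, k0=100.0)
        out = sw.collision_map(omega, p)
        assert out == pytest.approx(omega * math.cos(2 * theta0), rel=1e-14)
        # kinetic energy ratio is the Floquet multiplier cos^2(2 theta0)
        assert (out / omega) ** 2 == pytest.approx(p.floquet, rel=1e-12)


# ---------------------------------------------------------------------------
# four-bar geometry
# ---------------------------------------------------------------------------

class TestFourBar:
    def test_onset_angle(self, p12):
        assert psi_of_theta(p12.theta0, p12) == pytest.approx(p12.psi0, abs=1e-12)

    def test_release_happens_inside_the_step(self, p12, p6):
        for p in (p12, p6):
            assert -p.theta0 < p.theta_release < p.theta0
            assert psi_of_theta(p.theta_release, p) == pytest.approx(p.mu, abs=1e-10)

    def test_theta_psi_roundtrip(self, p12):
        for theta in np.linspace(p12.theta_release, p12.theta0, 7):
            psi = psi_of_theta(theta, p12)
            assert theta_of_psi(psi, p12) == pytest.approx(theta, abs=1e-12)

    def test_transmission_ratio_matches_finite_difference(self, p12):
        eps = 1e-7
        for theta in np.linspace(p12.theta_release, p12.theta0, 5):
            fd = (psi_of_theta(theta + eps, p12)
                  - psi_of_theta(theta - eps, p12)) / (2 * eps)
            assert dpsi_dtheta(theta, p12) == pytest.approx(fd, rel=1e-6)
            fd2 = (dpsi_dtheta(theta + eps, p12)
                   - dpsi_dtheta(theta - eps, p12)) / (2 * eps)
            assert d2psi_dtheta2(theta, p12) == pytest.approx(fd2, rel=1e-5)

    def test_infeasible_geometry_detected(self):
        # a tiny mu puts the release before double stance even starts
        with pytest.raises(sw.GeometryError):
            sw.WalkerParams(theta0=PI12, k0=100.0, mu=0.5).theta_release


# ---------------------------------------------------------------------------
# phase derivatives
# ---------------------------------------------------------------------------

class TestSingleStance:
    def test_upright_equilibrium(self, p12):
        state = sw.HybridState(sw.Phase.SINGLE_STANCE, 0.0, 0.0)
        assert sw.single_stance_derivatives(state, p12) == (0.0, 0.0)

    @given(theta=st.floats(-0.25, 0.25), thetadot=st.floats(-2.0, 2.0))
    def test_odd_symmetry(self, theta, thetadot):
        p = sw.WalkerParams(theta0=PI12, k0=100.0)
        _, a_pos = sw.single_stance_derivatives(
            sw.HybridState(sw.Phase.SINGLE_STANCE, theta, thetadot), p)
        _, a_neg = sw.single_stance_derivatives(
            sw.HybridState(sw.Phase.SINGLE_STANCE, -theta, thetadot), p)
        assert a_neg == pytest.approx(-a_pos, abs=1e-14)

    def test_energy_conserved_along_simulated_arc(self, p12):
        """Mechanical energy constant to relative 1e-8 over single stance."""
        rec, omega_pre = sw.integrate_step(
            sw.post_collision_state(1.34, p12), p12.k0, p12)
        theta_s = p12.theta_release
        omega_s = math.sqrt(thetadot_sq(theta_s, 1.34 ** 2, p12.k0, p12))
        e_start = (0.5 * p12.m * (p12.L * omega_s) ** 2
                   + p12.m * p12.g * p12.L * math.cos(theta_s))
        e_end = (0.5 * p12.m * (p12.L * omega_pre) ** 2
                 + p12.m * p12.g * p12.L * math.cos(p12.theta0))
        assert e_end == pytest.approx(e_start, rel=1e-8)


class TestDoubleStance:
    def test_only_gravity_at_release(self, p12):
        """At psi = mu the spring term vanishes from the acceleration."""
        theta = p12.theta_release
        j = dpsi_dtheta(theta, p12)
        state = sw.HybridState(sw.Phase.DOUBLE_STANCE, p12.mu, j * -1.0)
        _, psidd = sw.double_stance_derivatives(state, p12.k0, p12)
        gravity_only = j * (p12.g / p12.L) * math.sin(theta) \
            + d2psi_dtheta2(theta, p12) * (-1.0) ** 2
        assert psidd == pytest.approx(gravity_only, rel=1e-10)

    def test_power_balance(self, p12):
        """d(KE)/dt equals torque*psidot + gravity power along the phase.

        The kinetic-energy rate is estimated by central finite differences
        of the integrated trajectory; the residual must stay below
        1e-8 * m*g*L.
        """
        h = 1e-5
        psi, psidot = p12.psi0, dpsi_dtheta(p12.theta0, p12) * (-1.34)
        traj = [(psi, psidot)]
        for _ in range(400):
            # RK4 in the psi coordinate using the public derivative API
            def f(q, qd):
                return sw.double_stance_derivatives(
                    sw.HybridState(sw.Phase.DOUBLE_STANCE, q, qd),
                    p12.k0, p12)
            k1 = f(psi, psidot)
            k2 = f(psi + 0.5 * h * k1[0], psidot + 0.5 * h * k1[1])
            k3 = f(psi + 0.5 * h * k2[0], psidot + 0.5 * h * k2[1])
            k4 = f(psi + h * k3[0], psidot + h * k3[1])
            psi += h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6
            psidot += h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6
            traj.append((psi, psidot))

        def kinetic(q, qd):
            theta = theta_of_psi(q, p12)
            thetadot = qd / dpsi_dtheta(theta, p12)
            return 0.5 * p12.m * (p12.L * thetadot) ** 2

        tol = 1e-8 * p12.m * p12.g * p12.L
        for i in range(1, len(traj) - 1, 37):
            ke_rate = (kinetic(*traj[i + 1]) - kinetic(*traj[i - 1])) / (2 * h)
            q, qd = traj[i]
            theta = theta_of_psi(q, p12)
            thetadot = qd / dpsi_dtheta(theta, p12)
            power = (sw.ankle_torque(q, p12.k0, p12) * qd
                     + p12.m * p12.g * p12.L * math.sin(theta) * thetadot)
            assert abs(ke_rate - power) < tol

    def test_hip_trajectory_matches_constraint_projection_oracle(self, p12):
        """0.01 s of double stance agrees with a Cartesian DAE integration."""
        x = 1.34 ** 2
        h = 1e-5
        times, dae_pos = dae_hip_trajectory(x, p12.k0, p12, t_end=0.01, h=h)
        # reduced scalar integration through the psi API
        psi, psidot = p12.psi0, dpsi_dtheta(p12.theta0, p12) * (-math.sqrt(x))
        pos = [dae_pos[0].copy()]
        for _ in range(len(times) - 1):
            def f(q, qd):
                return sw.double_stance_derivatives(
                    sw.HybridState(sw.Phase.DOUBLE_STANCE, q, qd),
                    p12.k0, p12)
            k1 = f(psi, psidot)
            k2 = f(psi + 0.5 * h * k1[0], psidot + 0.5 * h * k1[1])
            k3 = f(psi + 0.5 * h * k2[0], psidot + 0.5 * h * k2[1])
            k4 = f(psi + h * k3[0], psidot + h * k3[1])
            psi += h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6
            psidot += h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6
            theta = theta_of_psi(psi, p12)
            pos.append(np.array([-p12.L * math.sin(theta),
                                 p12.L * math.cos(theta)]))
        err = np.max(np.linalg.norm(np.array(pos) - dae_pos, axis=1))
        assert err < 1e-6

    def test_singular_configuration_raises(self, p6):
        # straightened linkage (pivot, ankle, hip collinear): psi = pi
        c1 = p6.ground_link
        theta_lock = math.asin(
            (c1 ** 2 + p6.L ** 2 - (p6.l + p6.L) ** 2) / (2 * p6.L * c1))
        with pytest.raises(sw.GeometryError):
            dpsi_dtheta(theta_lock, p6)


# ---------------------------------------------------------------------------
# step integration
# ---------------------------------------------------------------------------

class TestIntegrateStep:
    def test_durations_match_quadrature_oracle(self, p12, p6):
        """RK4 + event bisection vs energy-conservation quadrature."""
        for p, x in ((p12, 1.7935), (p6, 4.0)):
            rec, omega_pre = sw.integrate_step(
                sw.post_collision_state(math.sqrt(x), p), p.k0, p)
            t_ds, t_tot, om = quad_step_durations(x, p.k0, p)
            assert rec.ds_duration == pytest.approx(t_ds, abs=1e-8)
            assert rec.duration == pytest.approx(t_tot, abs=1e-8)
            assert omega_pre == pytest.approx(om, rel=1e-9)

    def test_fixed_point_step_is_periodic(self, p12):
        """From the limit cycle, 100 consecutive steps repeat to 1e-9 s."""
        model = sw.ReturnMapModel.from_params(p12)
        omega = math.sqrt(model.fixed_point)
        durations = []
        for _ in range(100):
            rec, omega_pre = sw.integrate_step(
                sw.post_collision_state(omega, p12), p12.k0, p12)
            durations.append(rec.duration)
            omega = sw.collision_map(omega_pre, p12)
        assert np.ptp(durations) < 1e-9

    def test_tenfold_smaller_step_changes_little(self, p12):
        """Durations move by < 1e-6 s under h -> h/10 (integrator converged)."""
        x = 1.7935
        fine = sw.WalkerParams(**{**p12.to_dict(), "h": p12.h / 10})
        rec_h, _ = sw.integrate_step(
            sw.post_collision_state(math.sqrt(x), p12), p12.k0, p12)
        rec_f, _ = sw.integrate_step(
            sw.post_collision_state(math.sqrt(x), fine), fine.k0, fine)
        assert abs(rec_h.duration - rec_f.duration) < 1e-6
        assert abs(rec_h.ds_duration - rec_f.ds_duration) < 1e-6

    def test_work_energy_closure(self, p12):
        """dKE over the step equals the released spring work to < 1e-6 J."""
        x = 1.5
        rec, omega_pre = sw.integrate_step(
            sw.post_collision_state(math.sqrt(x), p12), p12.k0, p12)
        mL2 = p12.m * p12.L ** 2
        dke = 0.5 * mL2 * (omega_pre ** 2 - x)  # gravity nets to zero
        spring = 0.5 * p12.k0 * p12.spring_travel ** 2
        assert abs(dke - spring) < 1e-6
        # and the subsequent collision removes the (1 - cos^2 2theta0) share
        omega_next = sw.collision_map(omega_pre, p12)
        loss = 0.5 * mL2 * (omega_pre ** 2 - omega_next ** 2)
        assert loss == pytest.approx(
            0.5 * mL2 * omega_pre ** 2 * (1 - p12.floquet), rel=1e-12)

    def test_gait_failure_reported(self, p12):
        with pytest.raises(sw.GaitFailureError):
            sw.integrate_step(sw.post_collision_state(0.05, p12), p12.k0, p12)

    def test_nonpositive_k_rejected(self, p12):
        with pytest.raises(ValueError):
            sw.integrate_step(sw.post_collision_state(1.3, p12), 0.0, p12)


# ---------------------------------------------------------------------------
# whole walks
# ---------------------------------------------------------------------------

class TestSimulateWalk:
    def test_deterministic_walk_has_zero_cov(self, p12):
        series = sw.simulate_walk(p12, 20, noisy=False)
        assert np.ptp(series.intervals) < 1e-9
        assert sw.cov_percent(series) == pytest.approx(0.0, abs=1e-6)

    def test_noisy_walk_reproducible(self, p12):
        noisy = p12.with_noise(12.0 ** 2)
        a = sw.simulate_walk(noisy, 30, seed=42)
        b = sw.simulate_walk(noisy, 30, seed=42)
        c = sw.simulate_walk(noisy, 30, seed=43)
        assert np.array_equal(a.intervals, b.intervals)
        assert not np.array_equal(a.intervals, c.intervals)

    def test_stride_is_two_steps(self, p12):
        series = sw.simulate_walk(p12, 4, noisy=False)
        rec, _ = sw.integrate_step(
            sw.post_collision_state(
                math.sqrt(sw.ReturnMapModel.from_params(p12).fixed_point),
                p12), p12.k0, p12)
        assert series.intervals[0] == pytest.approx(2 * rec.duration, abs=1e-8)

    def test_failure_carries_partial_series(self):
        # a spring far too weak for this leg angle cannot sustain the gait
        weak = sw.WalkerParams(theta0=PI12, k0=5.0, sigma2=0.01)
        with pytest.raises(sw.GaitFailureError) as exc_info:
            sw.simulate_walk(weak, 10, seed=1)
        partial = exc_info.value.partial
        assert partial is not None and not partial.complete
        assert partial.failed_at == exc_info.value.stride_index

    def test_discard_drops_leading_strides(self, p12):
        noisy = p12.with_noise(12.0 ** 2)
        full = sw.simulate_walk(noisy, 20, seed=9)
        trimmed = sw.simulate_walk(noisy, 15, seed=9, discard=5)
        assert np.array_equal(trimmed.intervals, full.intervals[5:])


class TestAverageSpeed:
    def test_definition_single_stride(self, p12):
        stride_t = p12.stride_length / 1.35
        series = sw.StrideSeries(intervals=np.array([stride_t]))
        assert sw.average_speed(series, p12) == pytest.approx(1.35, rel=1e-12)

    def test_doubling_intervals_halves_speed(self, p12):
        series = sw.simulate_walk(p12, 5, noisy=False)
        slow = sw.StrideSeries(intervals=2 * series.intervals)
        assert sw.average_speed(slow, p12) == pytest.approx(
            sw.average_speed(series, p12) / 2, rel=1e-12)
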