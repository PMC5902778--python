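"""Geometry, Hill-curve and fiber-dynamics tests."""

import math

import numpy as np
import pytest

from myoadmit import (
    GeometryParams,
    HillParams,
    active_force_length,
    force_velocity,
    geometry,
    invert_force_velocity,
    isometric_state,
    joint_torque,
    moment_arm_gradient,
    optimal_fiber_length,
    passive_force_length,
    pennation,
    simulate_muscle,
    tendon_force,
)
from myoadmit.musculotendon import (
    MuscleState,
    _fiber_rhs,
    isometric_equilibrium,
)


class TestGeometry:
    def test_right_angle(self, geom):
        lmt, _ = geometry(math.pi / 2, geom)
        assert lmt == pytest.approx(math.hypot(geom.OA, geom.OB))

    @pytest.mark.parametrize("q", [0.5, 1.0, math.pi / 2, 2.0, 2.8])
    def test_moment_arm_matches_finite_difference(self, q, geom):
        h = 1e-6
        l1, _ = geometry(q - h, geom)
        l2, _ = geometry(q + h, geom)
        _, rmt = geometry(q, geom)
        assert rmt == pytest.approx((l2 - l1) / (2 * h), rel=1e-6)

    def test_small_angle_limit(self, geom):
        lmt, _ = geometry(1e-4, geom)
        assert lmt == pytest.approx(abs(geom.OA - geom.OB), abs=1e-6)

    def test_angle_domain(self, geom):
        with pytest.raises(ValueError):
            geometry(0.0, geom)
        with pytest.raises(ValueError):
            geometry(math.pi, geom)

    @pytest.mark.parametrize("q", [0.8, math.pi / 2, 2.2])
    def test_moment_arm_gradient_matches_finite_difference(self, q, geom):
        h = 1e-5
        _, r1 = geometry(q - h, geom)
        _, r2 = geometry(q + h, geom)
        assert moment_arm_gradient(q, geom) == pytest.approx(
            (r2 - r1) / (2 * h), rel=1e-5)


class TestPennation:
    def test_optimal_length_gives_optimal_angle(self, hill):
        assert pennation(hill.l0, hill) == pytest.approx(hill.phi0)

    def test_width_conservation(self, hill):
        for lm in np.linspace(0.5 * hill.l0, 1.5 * hill.l0, 7):
            phi = pennation(lm, hill)
            assert lm * math.sin(phi) == pytest.approx(hill.width, abs=1e-12)

    def test_long_fiber_limit(self, hill):
        assert pennation(1e3 * hill.l0, hill) == pytest.approx(0.0, abs=1e-4)

    def test_fiber_shorter_than_width_rejected(self, hill):
        with pytest.raises(ValueError):
            pennation(0.5 * hill.width, hill)


class TestHillCurves:
    def test_active_force_length_values(self):
        assert active_force_length(1.0) == pytest.approx(
            math.sin(0.734), rel=1e-12)
        # positive root of the quadratic argument
        assert active_force_length(1.22059) == pytest.approx(0.0, abs=1e-4)
        # argument equals pi/2 near l = 0.680
        assert active_force_length(0.68011) > 0.99999

    def test_force_velocity_continuity_and_landmarks(self):
        assert force_velocity(0.0) == 1.0
        assert abs(force_velocity(-1e-9) - 1.0) < 1e-8
        assert abs(force_velocity(+1e-9) - 1.0) < 1e-7
        assert force_velocity(-1.0) == 0.0
        assert force_velocity(-1.5) == 0.0
        assert abs(force_velocity(10.0) - 1.8) < 0.02 * 1.8

    def test_invert_force_velocity_round_trip(self):
        for f in np.linspace(0.01, 1.775, 60):
            assert force_velocity(invert_force_velocity(f)) == pytest.approx(
                f, abs=1e-10)
        assert invert_force_velocity(1.0) == 0.0
        assert invert_force_velocity(0.0) == -1.0

    def test_invert_force_velocity_warns_at_asymptote(self):
        with pytest.warns(RuntimeWarning):
            invert_force_velocity(1.85)

    def test_passive_force_length(self):
        assert passive_force_length(1.0) == 0.0
        assert passive_force_length(0.8) == 0.0
        assert passive_force_length(1.2) == pytest.approx(
            0.129 * (math.exp(0.905) - 1.0), rel=1e-12)
        l = np.linspace(1.0, 1.5, 50)
        assert np.all(np.diff(passive_force_length(l)) > 0)

    def test_optimal_fiber_length(self, hill):
        assert optimal_fiber_length(1.0, hill) == pytest.approx(hill.l0)
        assert optimal_fiber_length(0.0, hill) == pytest.approx(1.15 * hill.l0)
        assert optimal_fiber_length(0.5, hill) == pytest.approx(1.075 * hill.l0)


class TestTendon:
    def test_slack_tendon_carries_no_force(self, hill):
        assert tendon_force(hill.lst * 0.99, hill) == 0.0

    def test_branch_agreement_at_knee(self, hill):
        eps = 0.0127
        quad = 1480.3 * hill.Fmx * eps**2
        lin = (37.5 * eps - 0.2375) * hill.Fmx
        assert abs(quad - lin) < 1e-4 * hill.Fmx

    def test_linear_branch_value(self):
        p = HillParams(Fmx=1000.0, lst=0.2, l0=0.1, phi0=0.1)
        lt = p.lst * 1.02  # eps = 0.02
        assert tendon_force(lt, p) == pytest.approx(512.5, rel=1e-9)

    def test_continuous_and_nondecreasing(self, hill):
        lt = np.linspace(0.9 * hill.lst, 1.1 * hill.lst, 2000)
        f = tendon_force(lt, hill)
        d = np.diff(f)
        assert np.all(d >= 0)
        assert np.max(np.abs(d)) < 1e-2 * hill.Fmx  # no jumps


class TestFiberDynamics:
    def test_isometric_convergence_to_force_balance(self, hill, geom):
        fs, n = 1000.0, 3000
        a = np.full(n, 0.4)
        q = np.full(n, math.pi / 2)
        traj = simulate_muscle(a, q, fs, hill, geom)
        res = np.abs(traj.Ft - (traj.Fce + traj.Fpe) * np.cos(traj.phi))
        assert res[-1] < 1e-6 * hill.Fmx
        # residual along accepted steps (after the brief initial
        # transient where the velocity clamp may engage)
        assert np.all(res[500:] < 1e-5 * hill.Fmx)

    def test_zero_activation_zero_force_configuration(self, hill):
        # geometry chosen so lmt at 90 deg equals lst + l0 cos(phi0):
        # the slack-tendon, slack-fiber configuration
        L = hill.lst + hill.l0 * math.cos(hill.phi0)
        g = GeometryParams(OA=math.sqrt(L**2 - 0.045**2), OB=0.045)
        lm = isometric_equilibrium(0.0, math.pi / 2, hill, g)
        st, tq = isometric_state(0.0, math.pi / 2, hill, g)
        assert st.Ft == pytest.approx(0.0, abs=1e-9)
        assert st.Fpe == pytest.approx(0.0, abs=1e-9)
        assert hill.l0 * 0.999 <= lm <= 1.15 * hill.l0 * 1.001
        assert tq.Mp == pytest.approx(0.0, abs=1e-9)

    def test_adaptive_integration_matches_fixed_step_rk4_oracle(
            self, hill, geom):
        # independent fixed-step RK4 at 10x finer step
        fs = 200.0
        n = 400
        t = np.arange(n) / fs
        a = 0.05 + 0.45 * 0.5 * (1 - np.cos(2 * math.pi * np.clip(
            (t - 0.2) / 1.0, 0, 1)))
        q = np.full(n, math.pi / 2)
        traj = simulate_muscle(a, q, fs, hill, geom, lm_init="equilibrium")

        lmt, _ = geometry(math.pi / 2, geom)
        h = 1.0 / (10 * fs)
        lm = traj.lm[0]
        lm_oracle = [lm]
        for i in range(n - 1):
            for k in range(10):
                tt = t[i] + k * h

                def f(y, tt=tt):
                    ai = np.interp(tt, t, a)
                    return _fiber_rhs(y, ai, lmt, hill)[0]

                k1 = f(lm)
                k2 = f(lm + 0.5 * h * k1)
                k3 = f(lm + 0.5 * h * k2)
                k4 = f(lm + h * k3)
                lm += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            lm_oracle.append(lm)
        lm_oracle = np.array(lm_oracle)
        assert np.max(np.abs(traj.lm - lm_oracle) / lm_oracle) < 1e-4

    def test_width_conserved_along_trajectory(self, hill, geom):
        fs, n = 500.0, 1000
        a = np.clip(np.linspace(0, 1.2, n), 0, 1)
        q = math.pi / 2 - 0.3 * np.sin(np.linspace(0, 4, n))
        traj = simulate_muscle(a, q, fs, hill, geom, lm_init="equilibrium")
        assert np.allclose(traj.lm * np.sin(traj.phi), hill.width, atol=1e-12)

    def test_monotone_approach_to_isometric_torque(self, hill, geom):
        fs, n = 1000.0, 4000
        a = np.full(n, 0.6)
        q = np.full(n, math.pi / 2)
        traj = simulate_muscle(a, q, fs, hill, geom,
                               lm_init=0.9 * hill.l0)
        mp = traj.Mp[100:]
        diffs = np.diff(mp)
        # monotone (single-signed) approach and a vanishing derivative
        assert np.all(diffs <= 1e-9) or np.all(diffs >= -1e-9)
        assert abs(mp[-1] - mp[-2]) * fs < 1e-4  # |dMp/dt| -> 0

    def test_quasistatic_matches_ode_steady_state(self, hill, geom):
        fs, n = 100.0, 400
        a = np.full(n, 0.3)
        q = np.full(n, 2.0)
        qs = simulate_muscle(a, q, fs, hill, geom, method="quasistatic")
        ode = simulate_muscle(a, q, fs, hill, geom)
        assert qs.Mp[-1] == pytest.approx(ode.Mp[-1], rel=1e-4)


class TestJointTorque:
    def test_product_and_linearity(self):
        st = MuscleState(lm=0.1, lt=0.2, phi=0.05, v=0.0, l=1.0,
                         Fce=150.0, Fpe=50.0, Fm=200.0, Ft=200.0, Fmt=200.0)
        tq = joint_torque(st, rmt=0.05)
        assert tq.Mp == pytest.approx(10.0)
        st2 = MuscleState(lm=0.1, lt=0.2, phi=0.05, v=0.0, l=1.0,
                          Fce=300.0, Fpe=100.0, Fm=400.0, Ft=400.0, Fmt=400.0)
        assert joint_torque(st2, rmt=0.05).Mp == pytest.approx(2 * tq.Mp)
        st0 = MuscleState(lm=0.1, lt=0.2, phi=0.05, v=0.0, l=1.0,
                          Fce=0.0, Fpe=0.0, Fm=0.0, Ft=0.0, Fmt=0.0)
        assert joint_torque(st0, rmt=0.05).Mp == 0.0
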