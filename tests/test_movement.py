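"""Steering/velocity laws and movement integration."""

import math

import numpy as np
import pytest

from passdyn.movement import (
    AgentState,
    DegenerateGeometryError,
    GoalGeometry,
    SteeringParams,
    VelocityParams,
    goal_geometry,
    integrate_movement,
    step_state,
    steering_accel,
    velocity_accel,
    wrap_angle,
)
from passdyn.simulate import CALIBRATED_CV, initial_heading
from passdyn.task import Point2


class TestGoalGeometry:
    def test_straight_ahead(self):
        g = goal_geometry(Point2(0, 0), Point2(0, 1))
        assert g.distance == pytest.approx(1.0)
        assert g.goal_angle == pytest.approx(0.0)

    def test_3_4_5_triangle(self):
        g = goal_geometry(Point2(0, 0), Point2(3, 4))
        assert g.distance == pytest.approx(5.0)
        # signed angle from +y toward +x; magnitude matches arccos((Yg-y)/d)
        assert g.goal_angle == pytest.approx(0.6435011, abs=1e-6)
        assert abs(g.goal_angle) == pytest.approx(math.acos(4 / 5), abs=1e-12)

    def test_left_goal_negative_angle(self):
        g = goal_geometry(Point2(0, 0), Point2(-3, 4))
        assert g.goal_angle == pytest.approx(-0.6435011, abs=1e-6)

    def test_coincident_raises(self):
        with pytest.raises(DegenerateGeometryError):
            goal_geometry(Point2(1, 1), Point2(1, 1))


class TestSteeringAccel:
    def test_equilibrium(self):
        st = AgentState(Point2(0, 0), heading=0.3)
        g = GoalGeometry(distance=1.0, goal_angle=0.3)
        assert steering_accel(st, g, SteeringParams()) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # -k_g * err * (exp(-c1 d) + c2) with the literature-scale gains
        p = SteeringParams(b_g=3.25, k_g=7.5, c1=0.4, c2=0.4)
        st = AgentState(Point2(0, 0), heading=0.1, heading_rate=0.0)
        g = GoalGeometry(distance=1.0, goal_angle=0.0)
        expected = -7.5 * 0.1 * (math.exp(-0.4) + 0.4)
        assert steering_accel(st, g, p) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-0.8027, abs=5e-5)

    def test_pure_damping(self):
        p = SteeringParams()
        st = AgentState(Point2(0, 0), heading=0.5, heading_rate=1.2)
        g = GoalGeometry(distance=2.0, goal_angle=0.5)
        assert steering_accel(st, g, p) == pytest.approx(-p.b_g * 1.2)

    def test_error_wrapping(self):
        # a heading 2*pi away from the goal angle exerts no torque
        p = SteeringParams()
        st = AgentState(Point2(0, 0), heading=0.1 + 2 * math.pi)
        g = GoalGeometry(distance=1.0, goal_angle=0.1)
        assert steering_accel(st, g, p) == pytest.approx(0.0, abs=1e-9)


class TestVelocityAccel:
    def test_equilibrium(self):
        p = VelocityParams()
        v_eq = p.C_v * (1 - math.exp(-0.7))
        st = AgentState(Point2(0, 0), 0.0, speed=v_eq, speed_rate=0.0)
        assert velocity_accel(st, 0.7, p) == pytest.approx(0.0)

    def test_far_goal_drive_limit(self):
        p = VelocityParams()
        st = AgentState(Point2(0, 0), 0.0, speed=0.0, speed_rate=0.0)
        assert velocity_accel(st, 50.0, p) == pytest.approx(p.k_v * p.C_v, rel=1e-9)

    def test_goal_reached_decelerates(self):
        p = VelocityParams()
        st = AgentState(Point2(0, 0), 0.0, speed=0.8, speed_rate=0.0)
        assert velocity_accel(st, 0.0, p) == pytest.approx(-p.k_v * 0.8)


class TestStepState:
    def test_equilibrium_advances_position_only(self):
        p = VelocityParams()
        goal = Point2(0, 10)
        v_eq = p.C_v * (1 - math.exp(-10.0))
        st = AgentState(Point2(0, 0), heading=0.0, speed=v_eq)
        out = step_state(st, goal, SteeringParams(), p, dt=0.01)
        assert out.heading == pytest.approx(0.0)
        assert out.pos.y == pytest.approx(v_eq * 0.01)
        assert out.pos.x == pytest.approx(0.0)

    def test_noise_determinism(self):
        st = AgentState(Point2(0, 0), heading=0.2, speed=0.5)
        outs = [
            step_state(
                st, Point2(1, 1), SteeringParams(), VelocityParams(), 0.01,
                heading_noise=0.02, rng=np.random.default_rng(11),
            )
            for _ in range(2)
        ]
        assert outs[0] == outs[1]

    def test_speed_clamped_nonnegative(self):
        st = AgentState(Point2(0, 0.9), heading=0.0, speed=0.001, speed_rate=-10.0)
        out = step_state(st, Point2(0, 1), SteeringParams(), VelocityParams(), 0.01)
        assert out.speed >= 0.0


def _rhs(state, goal, sp, vp):
    """Independent right-hand side of the six-dimensional system."""
    h, hr, x, y, v, vr = state
    dx, dy = goal.x - x, goal.y - y
    d = math.hypot(dx, dy)
    theta = math.atan2(dx, dy)
    err = wrap_angle(h - theta)
    return np.array(
        [
            hr,
            -sp.b_g * hr - sp.k_g * err * (math.exp(-sp.c1 * d) + sp.c2),
            v * math.sin(h),
            v * math.cos(h),
            vr,
            -vp.b_v * vr - vp.k_v * (v - vp.C_v * (1 - math.exp(-d))),
        ]
    )


class TestIntegration:
    def test_aimed_start_goes_straight(self, task):
        goal = task.target(10)
        g = goal_geometry(Point2(0, 0), goal)
        st = AgentState(Point2(0, 0), heading=g.goal_angle)
        traj = integrate_movement(st, goal, velocity=VelocityParams(C_v=2.5))
        assert traj.arrived
        nt = traj.positions()
        chord = goal.as_array() / np.linalg.norm(goal.as_array())
        off = nt @ np.array([-chord[1], chord[0]])
        assert np.max(np.abs(off)) < 5e-3

    def test_offset_start_curves_with_matching_sign(self, task):
        goal = task.target(10)
        g = goal_geometry(Point2(0, 0), goal)
        for sign in (+1, -1):
            st = AgentState(Point2(0, 0), heading=g.goal_angle + sign * math.radians(20))
            traj = integrate_movement(st, goal, velocity=VelocityParams(C_v=2.5))
            assert traj.arrived
            p = traj.positions()
            u = goal.as_array() / np.linalg.norm(goal.as_array())
            left = np.array([-u[1], u[0]])  # left of the chord direction
            area = np.trapezoid(p @ left, p @ u)
            # heading offset toward +x (clockwise from the chord) bulges right
            assert math.copysign(1.0, area) == -sign

    def test_max_steps_flags_non_arrival(self):
        st = AgentState(Point2(0, 0), heading=0.0)
        traj = integrate_movement(st, Point2(0, 1), max_steps=1)
        assert not traj.arrived
        assert len(traj) == 2

    def test_start_inside_stop_radius_rejected(self):
        st = AgentState(Point2(0, 0), heading=0.0)
        with pytest.raises(DegenerateGeometryError):
            integrate_movement(st, Point2(0, 0.01))

    def test_all_task_pairs_arrive_noise_free(self, task):
        vp = VelocityParams(C_v=CALIBRATED_CV["target"])
        for i in range(1, 6):
            h = initial_heading("target", i, task=task)
            for tg in range(1, 21):
                traj = integrate_movement(
                    AgentState(task.pickup(i), h), task.target(tg), velocity=vp
                )
                assert traj.arrived, (i, tg)
                assert traj.final_goal_distance <= 0.04

    def test_speed_profile_single_peaked_first_half(self, task):
        vp = VelocityParams(C_v=CALIBRATED_CV["target"])
        n_ok = 0
        n = 0
        for i in range(1, 6):
            h = initial_heading("target", i, task=task)
            for tg in range(1, 21):
                traj = integrate_movement(
                    AgentState(task.pickup(i), h), task.target(tg), velocity=vp
                )
                dv = np.diff(traj.speed)
                sign_changes = np.sum(np.diff(np.sign(dv[dv != 0])) != 0)
                peak_at = np.argmax(traj.speed) / (len(traj) - 1)
                n += 1
                n_ok += (sign_changes <= 1) and (peak_at < 0.5)
        assert n_ok / n >= 0.95

    def test_heading_error_decays_monotonically_on_transport(self, task):
        # long (transport-scale) movements null the heading error to < 1 deg
        vp = VelocityParams(C_v=CALIBRATED_CV["target"])
        for i in (1, 3, 5):
            h = initial_heading("target", i, task=task)
            traj = integrate_movement(
                AgentState(task.pickup(i), h), task.target(10), velocity=vp
            )
            errs = np.array(
                [
                    abs(
                        wrap_angle(
                            traj.heading[k]
                            - goal_geometry(
                                Point2(traj.x[k], traj.y[k]), traj.goal
                            ).goal_angle
                        )
                    )
                    for k in range(len(traj))
                ]
            )
            assert errs[-1] < math.radians(1.0)
            assert np.all(np.diff(errs) <= 1e-9)

    def test_euler_matches_reference_integrator(self, task):
        # oracle: independent RK4 at dt=1e-4 of the same equations
        sp = SteeringParams()
        vp = VelocityParams(C_v=CALIBRATED_CV["target"])
        goal = task.target(10)
        h0 = initial_heading("target", 3, task=task)
        start = task.pickup(3)

        traj = integrate_movement(AgentState(start, h0), goal, sp, vp)
        T = traj.t[-1]

        state = np.array([h0, 0.0, start.x, start.y, 0.0, 0.0])
        dt = 1e-4
        for _ in range(int(round(T / dt))):
            k1 = _rhs(state, goal, sp, vp)
            k2 = _rhs(state + 0.5 * dt * k1, goal, sp, vp)
            k3 = _rhs(state + 0.5 * dt * k2, goal, sp, vp)
            k4 = _rhs(state + dt * k3, goal, sp, vp)
            state = state + (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            state[4] = max(state[4], 0.0)
        gap = math.hypot(state[2] - traj.x[-1], state[3] - traj.y[-1])
        assert gap < 0.01
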