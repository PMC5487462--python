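"""Calibration of the free model parameters against observed summaries.

Two calibrations are provided:

* ``calibrate_velocity`` fixes the per-class speed scales C_v so that the
  mean peak speed over a representative set of noise-free movements of
  each class matches the observed means (1.46 m/s pickup, 1.75 m/s pass,
  1.80 m/s target).  The representative sets mirror the movements a
  session actually produces: ready->pickup for all five pickups; pickup ->
  each of the fifteen no-pass targets; pickup -> each pass anchor.  Mean
  peak speed is monotone in C_v, so a bracketing bisection (a grid search
  refined to tolerance) suffices.

* ``calibrate_decision_params`` (re-exported from the decision module)
  solves sigma and delta so the analytic sweep thresholds
  sigma +- alpha_c/delta land on the observed ascending/descending
  transition E/A ratios (0.853 / 0.797).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .decision import calibrate_decision_params
from .movement import AgentState, SteeringParams, VelocityParams, integrate_movement
from .simulate import IntegrationSettings, InitialAngleModel, initial_heading
from .task import Point2, TaskSpace, build_task_space

__all__ = [
    "PEAK_SPEED_TARGETS",
    "representative_movements",
    "mean_peak_speed",
    "calibrate_velocity",
    "calibrate_decision_params",
]

#: Observed mean peak speeds per movement class (m/s).
PEAK_SPEED_TARGETS: dict[str, float] = {"pickup": 1.46, "pass": 1.75, "target": 1.80}

#: Targets reachable without passing under the default decision calibration
#: (E/A below the ascending transition): indices 1..15.
_NO_PASS_TARGETS = range(1, 16)


def representative_movements(
    movement_class: str, task: TaskSpace, angles: InitialAngleModel
) -> list[tuple[AgentState, Point2]]:
    """Noise-free (start state, goal) pairs representative of a class."""
    out: list[tuple[AgentState, Point2]] = []
    ready = Point2(0.0, 0.0)
    for i in range(1, 6):
        if movement_class == "pickup":
            h = initial_heading("pickup", i, angles, task=task)
            out.append((AgentState(ready, h), task.pickup(i)))
        elif movement_class == "target":
            h = initial_heading("target", i, angles, task=task)
            for tg in _NO_PASS_TARGETS:
                out.append((AgentState(task.pickup(i), h), task.target(tg)))
        elif movement_class == "pass":
            h = initial_heading("pass", i, angles, task=task)
            for strategy in ("near_target", "near_confederate"):
                out.append((AgentState(task.pickup(i), h), task.pass_anchor(strategy)))
        else:
            raise ValueError(f"unknown movement class {movement_class!r}")
    return out


def mean_peak_speed(
    movement_class: str,
    C_v: float,
    task: TaskSpace,
    steering: SteeringParams,
    velocity: VelocityParams,
    angles: InitialAngleModel,
    integration: IntegrationSettings,
) -> float:
    """Mean noise-free peak speed of a class's representative movements."""
    vp = replace(velocity, C_v=C_v)
    peaks = []
    for start, goal in representative_movements(movement_class, task, angles):
        traj = integrate_movement(
            start,
            goal,
            steering,
            vp,
            dt=integration.dt,
            stop_radius=integration.stop_radius,
            max_steps=integration.max_steps,
            movement_class=movement_class,  # type: ignore[arg-type]
        )
        peaks.append(traj.peak_speed)
    return float(np.mean(peaks))


def calibrate_velocity(
    task: TaskSpace | None = None,
    steering: SteeringParams | None = None,
    velocity: VelocityParams | None = None,
    angles: InitialAngleModel | None = None,
    integration: IntegrationSettings | None = None,
    targets: dict[str, float] | None = None,
    *,
    bracket: tuple[float, float] = (0.5, 20.0),
    tol: float = 1e-3,
) -> dict[str, VelocityParams]:
    """Solve C_v per movement class so mean peak speeds hit their targets.

    Returns a dict of VelocityParams (b_v, k_v copied from ``velocity``)
    keyed by movement class.  Raises if a target lies outside the bracket.
    """
    task = task or build_task_space()
    steering = steering or SteeringParams()
    velocity = velocity or VelocityParams()
    angles = angles or InitialAngleModel()
    integration = integration or IntegrationSettings()
    targets = targets or PEAK_SPEED_TARGETS

    out: dict[str, VelocityParams] = {}
    for cls, target in targets.items():
        lo, hi = bracket
        f_lo = mean_peak_speed(cls, lo, task, steering, velocity, angles, integration)
        f_hi = mean_peak_speed(cls, hi, task, steering, velocity, angles, integration)
        if not (f_lo < target < f_hi):
            raise ValueError(
                f"peak-speed target {target} m/s for {cls!r} outside bracket "
                f"[{f_lo:.3f}, {f_hi:.3f}]"
            )
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if (
                mean_peak_speed(cls, mid, task, steering, velocity, angles, integration)
                < target
            ):
                lo = mid
            else:
                hi = mid
        out[cls] = replace(velocity, C_v=0.5 * (lo + hi))
    return out
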