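"""Bistable pass/no-pass action selection.

The decision variable x evolves under the normal form of a one-dimensional
cusp system,

    xdot = -alpha + x - x**3,

whose control parameter alpha is an affine re-normalisation of the E/A
ratio (target distance over reach):

    alpha = (sigma - ea) * delta.

For |alpha| < alpha_c = 2 / (3 sqrt(3)) ~ 0.3849 the system is bistable
(two stable fixed points separated by an unstable one), producing
hysteresis: which attractor is reached depends on the previous state, which
is carried from trial to trial.  At |alpha| = alpha_c a saddle-node
bifurcation annihilates one stable branch and the decision becomes
obligatory.  Convergence onto the positive branch is read as *pass*, onto
the negative branch as *no pass*; with the affine map above, distant targets
(large ea) give alpha < -alpha_c and therefore passes.

The corresponding potential (with xdot = -dV/dx) is

    V(x) = alpha*x - x**2/2 + x**4/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DecisionParams",
    "DecisionState",
    "FixedPoint",
    "FixedPointSet",
    "compute_alpha",
    "flow",
    "potential",
    "fixed_points",
    "critical_alpha",
    "decide",
    "sweep_hysteresis",
    "hysteresis_loop",
    "calibrate_decision_params",
]

Mode = Literal["pass", "no_pass", "unset"]

#: Default transition-centre E/A and scaling, calibrated so the bistable
#: band [sigma - alpha_c/delta, sigma + alpha_c/delta] spans the observed
#: ascending/descending transition ratios 0.853 and 0.797.
DEFAULT_SIGMA = 0.825
DEFAULT_DELTA = 2.0 / (3.0 * math.sqrt(3.0)) / 0.028  # ~13.75


@dataclass(frozen=True)
class DecisionParams:
    """Mapping from E/A ratio to the decision control parameter alpha.

    ``affordance_distance_mode`` selects how the E/A ratio is computed by
    callers: from the target's y distance over reach (the empirical
    definition, default) or from the Euclidean hand-target distance at
    decision time.
    """

    sigma: float = DEFAULT_SIGMA
    delta: float = DEFAULT_DELTA
    affordance_distance_mode: Literal[
        "target_y_over_reach", "euclidean_hand_target"
    ] = "target_y_over_reach"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")


@dataclass
class DecisionState:
    """Carried decision state: x and the last resolved mode."""

    x: float = 0.0
    last_mode: Mode = "unset"

    def __post_init__(self) -> None:
        if not math.isfinite(self.x):
            raise ValueError(f"decision state must be finite, got {self.x}")


@dataclass(frozen=True)
class FixedPoint:
    x: float
    stable: bool


@dataclass(frozen=True)
class FixedPointSet:
    """Real fixed points of xdot = -alpha + x - x^3, sorted ascending."""

    alpha: float
    roots: tuple[FixedPoint, ...]

    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r.x for r in self.roots if r.stable)


def compute_alpha(ea: float, p: DecisionParams | None = None) -> float:
    """Control parameter alpha = (sigma - ea) * delta."""
    p = p or DecisionParams()
    return (p.sigma - ea) * p.delta


def flow(x: float, alpha: float) -> float:
    """Right-hand side of the decision dynamics: -alpha + x - x^3."""
    return -alpha + x - x * x * x


def potential(x: float, alpha: float) -> float:
    """Potential V with xdot = -dV/dx: alpha*x - x^2/2 + x^4/4."""
    return alpha * x - 0.5 * x * x + 0.25 * x ** 4


def critical_alpha() -> float:
    """Saddle-node value alpha_c = 2/(3*sqrt(3)) ~ 0.3849.

    At +-alpha_c the conditions x - x^3 = alpha and 1 - 3x^2 = 0 hold
    simultaneously and a stable/unstable pair annihilates.
    """
    return 2.0 / (3.0 * math.sqrt(3.0))


def fixed_points(alpha: float) -> FixedPointSet:
    """Real roots of x - x^3 = alpha with linear-stability labels.

    A root is stable iff the linearisation 1 - 3x^2 is negative.  At the
    saddle-node itself the degenerate root (1 - 3x^2 = 0) is marginal and
    labelled unstable.
    """
    roots = np.roots([1.0, 0.0, -1.0, alpha])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    # collapse numerically split double roots at the saddle-node
    keep: list[float] = []
    for r in real:
        if not keep or abs(r - keep[-1]) > 1e-7:
            keep.append(float(r))
    fps = tuple(FixedPoint(r, stable=(1.0 - 3.0 * r * r) < 0.0) for r in keep)
    return FixedPointSet(alpha=alpha, roots=fps)


def _rk4(x: float, alpha: float, n_steps: int, dt: float) -> float:
    """Fixed-step RK4 integration of the cubic flow."""
    for _ in range(n_steps):
        k1 = -alpha + x - x * x * x
        x2 = x + 0.5 * dt * k1
        k2 = -alpha + x2 - x2 * x2 * x2
        x3 = x + 0.5 * dt * k2
        k3 = -alpha + x3 - x3 * x3 * x3
        x4 = x + dt * k3
        k4 = -alpha + x4 - x4 * x4 * x4
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return x


def decide(
    state: DecisionState,
    alpha: float,
    *,
    n_steps: int = 1500,
    dt: float = 0.005,
    eps: float = 1e-3,
) -> tuple[Mode, DecisionState]:
    """Integrate the decision dynamics and read off the selected mode.

    The flow is integrated from the carried state ``state.x`` for
    ``n_steps`` fixed RK4 steps of ``dt``; the end state determines the
    mode (positive branch = pass, negative branch = no pass) and is
    returned for carry-over into the next trial.  If the end state is
    unresolved (|x| < eps) the previous mode is retained (no-pass when
    there is none).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    x_end = _rk4(state.x, alpha, n_steps, dt)
    if x_end > eps:
        mode: Mode = "pass"
    elif x_end < -eps:
        mode = "no_pass"
    else:
        mode = state.last_mode if state.last_mode != "unset" else "no_pass"
    return mode, DecisionState(x=x_end, last_mode=mode)


def sweep_hysteresis(
    ea_values: Sequence[float],
    p: DecisionParams | None = None,
    *,
    state: DecisionState | None = None,
    n_steps: int = 1500,
    dt: float = 0.005,
) -> float | None:
    """Run decisions along a monotone E/A sequence with state carry-over.

    Returns the E/A value at which the mode first flips, or ``None`` if no
    flip occurs within the range.  An ascending sweep flips at a higher E/A
    than a descending one (hysteresis).
    """
    ea = np.asarray(ea_values, dtype=float)
    if len(ea) < 3:
        raise ValueError("need at least 3 E/A values")
    d = np.diff(ea)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("E/A sequence must be strictly monotone")
    p = p or DecisionParams()
    state = state or DecisionState()
    first_mode: Mode | None = None
    for v in ea:
        mode, state = decide(state, compute_alpha(float(v), p), n_steps=n_steps, dt=dt)
        if first_mode is None:
            first_mode = mode
        elif mode != first_mode:
            return float(v)
    return None


def hysteresis_loop(
    ea_min: float,
    ea_max: float,
    n: int = 601,
    p: DecisionParams | None = None,
) -> tuple[float | None, float | None]:
    """Transition E/A of an ascending and a descending fine-grid sweep."""
    grid = np.linspace(ea_min, ea_max, n)
    up = sweep_hysteresis(grid, p)
    down = sweep_hysteresis(grid[::-1], p)
    return up, down


def calibrate_decision_params(
    up_transition_ea: float = 0.853,
    down_transition_ea: float = 0.797,
) -> DecisionParams:
    """Solve (sigma, delta) from observed sweep transition ratios.

    The analytic sweep thresholds are sigma +- alpha_c/delta, so
    sigma is their midpoint and delta = alpha_c / half-width.
    """
    if up_transition_ea <= down_transition_ea:
        raise ValueError("ascending transition must exceed descending")
    half = 0.5 * (up_transition_ea - down_transition_ea)
    return DecisionParams(
        sigma=0.5 * (up_transition_ea + down_transition_ea),
        delta=critical_alpha() / half,
    )
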