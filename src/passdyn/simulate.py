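"""Trial, session and experiment simulation.

Each trial runs the serial pipeline: ready -> pickup movement -> action
selection -> transport movement to either the (jittered) pass anchor or the
target, depending on the decision.  A session is 600 trials (three blocks:
ordered, random, ordered) driven by one RNG stream with a documented draw
order (initial angle, per-step heading noise, pass jitter); the decision
state is carried from trial to trial and reset only at session start.

Initial movement angles are not aimed at the goal: human reaches leave the
pickup with a stereotyped direction that depends on the pickup location but
not on the final goal, and the observed path curvature follows from that.
The initial-angle model interpolates the observed mean angles across the
five action-scaled pickup locations — linearly for pickup movements, with a
saturating exponential for pass/target movements (the change per unit pickup
distance shrinks as distance grows) — and adds uniform noise of +-20 deg.

Angle conventions: printed analysis angles are degrees from the +x table
axis.  For pass/target movements they are counter-clockwise with y away
from the actor (positive angles point away from the actor's body); for
pickup movements the printed angles are read mirrored (positive toward the
body), the unique orientation that reproduces both observed curvature
patterns (pickup curvature flipping from positive to negative with pickup
distance, and transport paths dipping toward the actor).  The model heading
phi (from +y toward +x) is phi = 90 deg + a for pickup movements and
phi = 90 deg - a for pass/target movements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .decision import DecisionParams, DecisionState, Mode, compute_alpha, decide
from .movement import (
    AgentState,
    MovementClass,
    SteeringParams,
    Trajectory,
    VelocityParams,
    integrate_movement,
)
from .task import (
    BlockSchedule,
    FrameConfig,
    Point2,
    SchedulePlans,
    TaskSpace,
    TrialSpec,
    build_schedule,
    build_task_space,
    to_participant_frame,
)

__all__ = [
    "InitialAngleModel",
    "PassJitter",
    "IntegrationSettings",
    "SimParams",
    "TrialResult",
    "SessionResult",
    "PassStrategy",
    "default_velocity_params",
    "initial_angle_deg",
    "initial_heading",
    "sample_pass_location",
    "run_trial",
    "run_session",
    "run_experiment",
    "session_seeds",
]

PassStrategy = Literal["near_target", "near_confederate"]

#: Per-class speed scales C_v (m/s), calibrated so noise-free representative
#: movements of each class reach the observed mean peak speeds
#: 1.46 (pickup), 1.75 (pass), 1.80 (target) m/s.
CALIBRATED_CV: dict[str, float] = {"pickup": 5.612, "pass": 4.144, "target": 2.568}


def default_velocity_params() -> dict[str, VelocityParams]:
    """Calibrated speed-law parameters per movement class."""
    return {cls: VelocityParams(C_v=cv) for cls, cv in CALIBRATED_CV.items()}


@dataclass(frozen=True)
class InitialAngleModel:
    """Initial movement direction as a function of the pickup location.

    Endpoint angles are in the printed analysis convention (degrees from
    +x); the first element of each pair belongs to the nearest pickup
    (label 0.2), the second to the farthest (label 1.0).
    """

    pickup_endpoints_deg: tuple[float, float] = (185.88, 201.59)
    pass_endpoints_deg: tuple[float, float] = (31.21, -35.15)
    target_endpoints_deg: tuple[float, float] = (31.35, -33.89)
    saturation_rate: float = 2.0
    noise_halfwidth_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_halfwidth_deg < 0:
            raise ValueError("noise halfwidth must be >= 0")
        if self.saturation_rate <= 0:
            raise ValueError("saturation rate must be positive")

    def mean_angle_deg(self, movement_class: MovementClass, label: float) -> float:
        """Mean initial angle (analysis convention) at a pickup E/A label."""
        u = (label - 0.2) / 0.8
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"pickup label {label} outside 0.2..1.0")
        if movement_class == "pickup":
            a0, a1 = self.pickup_endpoints_deg
            return a0 + (a1 - a0) * u
        if movement_class == "pass":
            a0, a1 = self.pass_endpoints_deg
        elif movement_class == "target":
            a0, a1 = self.target_endpoints_deg
        else:
            raise ValueError(f"unknown movement class {movement_class!r}")
        k = self.saturation_rate
        w = (1.0 - math.exp(-k * u)) / (1.0 - math.exp(-k))
        return a0 + (a1 - a0) * w


def _heading_from_angle(a_deg: float, movement_class: MovementClass) -> float:
    """Convert a printed-convention angle to the model heading (radians).

    Pickup angles are mirrored (see module docstring); pass/target are
    standard counter-clockwise from +x.
    """
    if movement_class == "pickup":
        return math.radians(90.0 + a_deg)
    return math.radians(90.0 - a_deg)


def initial_angle_deg(
    movement_class: MovementClass,
    pickup_index: int,
    model: InitialAngleModel | None = None,
    rng: np.random.Generator | None = None,
    *,
    task: TaskSpace | None = None,
) -> float:
    """Initial movement angle in the printed analysis convention (degrees).

    Deterministic mean from the endpoint-interpolation model plus uniform
    noise in +-noise_halfwidth (omitted when ``rng`` is None).
    """
    model = model or InitialAngleModel()
    task = task or build_task_space()
    label = task.pickup_label(pickup_index)
    a = model.mean_angle_deg(movement_class, label)
    if rng is not None and model.noise_halfwidth_deg > 0:
        a += rng.uniform(-model.noise_halfwidth_deg, model.noise_halfwidth_deg)
    return a


def initial_heading(
    movement_class: MovementClass,
    pickup_index: int,
    model: InitialAngleModel | None = None,
    rng: np.random.Generator | None = None,
    *,
    task: TaskSpace | None = None,
) -> float:
    """Initial model heading (radians, from +y) for a sub-task movement."""
    a = initial_angle_deg(movement_class, pickup_index, model, rng, task=task)
    return _heading_from_angle(a, movement_class)


@dataclass(frozen=True)
class PassJitter:
    """Lognormal radial scatter applied to the pass anchor.

    The release point is the anchor plus a radius drawn from
    LogNormal(log_mu, log_sigma) in a uniformly random direction, clipped
    to the table.  Defaults give a median offset of 5 cm, emulating the
    within-cluster spread of human release points.
    """

    log_mu: float = math.log(0.05)
    log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be >= 0")


def sample_pass_location(
    anchor: Point2,
    jitter: PassJitter,
    rng: np.random.Generator,
    frame: FrameConfig | None = None,
) -> Point2:
    """Draw a jittered release location around a table-frame anchor.

    Draw order: radius, then direction.  The result is clipped to the
    table bounds.
    """
    frame = frame or FrameConfig()
    if not frame.contains(anchor):
        raise ValueError(f"pass anchor {anchor} outside the table")
    r = rng.lognormal(mean=jitter.log_mu, sigma=jitter.log_sigma)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    lx, ly = frame.table_size
    x = min(max(anchor.x + r * math.cos(phi), 0.0), lx)
    y = min(max(anchor.y + r * math.sin(phi), 0.0), ly)
    return Point2(x, y)


@dataclass(frozen=True)
class IntegrationSettings:
    """Numerical settings for movement and decision integration."""

    dt: float = 0.01
    stop_radius: float = 0.04
    max_steps: int = 5000
    heading_noise_deg: float = 1.14
    decision_steps: int = 1500
    decision_dt: float = 0.005

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.decision_dt <= 0:
            raise ValueError("integration steps must be positive")
        if self.max_steps <= 0 or self.decision_steps < 1:
            raise ValueError("step counts must be positive")
        if self.stop_radius <= 0:
            raise ValueError("stop radius must be positive")
        if self.heading_noise_deg < 0:
            raise ValueError("heading noise must be >= 0")


@dataclass(frozen=True)
class SimParams:
    """Full parameter bundle for a simulated session."""

    steering: SteeringParams = field(default_factory=SteeringParams)
    velocity: dict[str, VelocityParams] = field(default_factory=default_velocity_params)
    decision: DecisionParams = field(default_factory=DecisionParams)
    angles: InitialAngleModel = field(default_factory=InitialAngleModel)
    jitter: PassJitter = field(default_factory=PassJitter)
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)
    carry_across_blocks: bool = True

    def velocity_for(self, movement_class: str) -> VelocityParams:
        try:
            return self.velocity[movement_class]
        except KeyError:
            raise KeyError(f"no velocity parameters for class {movement_class!r}")


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    spec: TrialSpec
    decision: Mode
    ea_used: float
    alpha: float
    decision_x_end: float
    pass_location: Point2 | None
    pickup_trajectory: Trajectory
    transport_trajectory: Trajectory

    def __post_init__(self) -> None:
        if (self.decision == "pass") != (self.pass_location is not None):
            raise ValueError("pass_location must be present iff decision is pass")

    @property
    def arrived(self) -> bool:
        return self.pickup_trajectory.arrived and self.transport_trajectory.arrived


@dataclass
class SessionResult:
    """One simulated 600-trial session."""

    schedule: BlockSchedule
    trials: list[TrialResult]
    pass_strategy: PassStrategy
    seed: int
    task: TaskSpace
    params: SimParams

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.schedule.trials):
            raise ValueError("trial count must equal schedule length")

    def decisions(self) -> np.ndarray:
        """0/1 array of no-pass/pass decisions in trial order."""
        return np.array([1 if t.decision == "pass" else 0 for t in self.trials])


def run_trial(
    spec: TrialSpec,
    task: TaskSpace,
    decision_state: DecisionState,
    params: SimParams,
    rng: np.random.Generator,
    pass_strategy: PassStrategy = "near_target",
) -> tuple[TrialResult, DecisionState]:
    """Simulate one trial; returns the result and the carried decision state.

    Pipeline: (1) integrate the ready->pickup movement; (2) compute the E/A
    ratio of the trial's target, map it to alpha and run the decision
    dynamics from the carried state; (3) integrate the transport movement
    from the pickup to the jittered pass anchor or the target accordingly.
    """
    it = params.integration
    noise_rad = math.radians(it.heading_noise_deg)
    ready = Point2(0.0, 0.0)
    pickup = task.pickup(spec.pickup_index)
    target = task.target(spec.target_index)

    start = AgentState(
        ready, initial_heading("pickup", spec.pickup_index, params.angles, rng, task=task)
    )
    pickup_traj = integrate_movement(
        start,
        pickup,
        params.steering,
        params.velocity_for("pickup"),
        dt=it.dt,
        stop_radius=it.stop_radius,
        max_steps=it.max_steps,
        heading_noise=noise_rad,
        rng=rng,
        movement_class="pickup",
    )
    hand = Point2(pickup_traj.x[-1], pickup_traj.y[-1])

    if params.decision.affordance_distance_mode == "euclidean_hand_target":
        ea = hand.distance_to(target) / task.reach
    else:
        ea = target.y / task.reach
    alpha = compute_alpha(ea, params.decision)
    mode, new_state = decide(
        decision_state, alpha, n_steps=it.decision_steps, dt=it.decision_dt
    )

    if mode == "pass":
        cls: MovementClass = "pass"
        anchor_table = (
            task.pass_anchor_near_target
            if pass_strategy == "near_target"
            else task.pass_anchor_near_confederate
        )
        jittered = sample_pass_location(anchor_table, params.jitter, rng, task.frame)
        goal = to_participant_frame(jittered, task.frame)
        pass_location: Point2 | None = goal
    else:
        cls = "target"
        goal = target
        pass_location = None

    transport_start = AgentState(
        hand, initial_heading(cls, spec.pickup_index, params.angles, rng, task=task)
    )
    transport_traj = integrate_movement(
        transport_start,
        goal,
        params.steering,
        params.velocity_for(cls),
        dt=it.dt,
        stop_radius=it.stop_radius,
        max_steps=it.max_steps,
        heading_noise=noise_rad,
        rng=rng,
        movement_class=cls,
    )
    result = TrialResult(
        spec=spec,
        decision=mode,
        ea_used=ea,
        alpha=alpha,
        decision_x_end=new_state.x,
        pass_location=pass_location,
        pickup_trajectory=pickup_traj,
        transport_trajectory=transport_traj,
    )
    return result, new_state


def run_session(
    schedule: BlockSchedule | None = None,
    task: TaskSpace | None = None,
    params: SimParams | None = None,
    seed: int = 0,
    pass_strategy: PassStrategy = "near_target",
) -> SessionResult:
    """Simulate a full session (600 trials) with one RNG stream.

    The decision state starts at x = 0 on trial 1 and is carried across
    block boundaries (configurable via ``params.carry_across_blocks``).
    """
    task = task or build_task_space()
    schedule = schedule or build_schedule(seed=seed)
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    state = DecisionState()
    results: list[TrialResult] = []
    prev_block = 1
    for spec in schedule.trials:
        if spec.block_index != prev_block and not params.carry_across_blocks:
            state = DecisionState()
        prev_block = spec.block_index
        res, state = run_trial(spec, task, state, params, rng, pass_strategy)
        results.append(res)
    return SessionResult(
        schedule=schedule,
        trials=results,
        pass_strategy=pass_strategy,
        seed=seed,
        task=task,
        params=params,
    )


def session_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent session seeds (< 2**31) from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_experiment(
    n_sessions: int = 8,
    task: TaskSpace | None = None,
    params: SimParams | None = None,
    seeds: Sequence[int] | None = None,
    base_seed: int = 0,
    plans: SchedulePlans | None = None,
) -> list[SessionResult]:
    """Simulate a set of sessions, half per pass-location strategy.

    The first half of the sessions release near the target-side anchor and
    the second half near the partner's hand (4 and 4 by default).  Each
    session gets its own seed (hence its own random block).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    task = task or build_task_space()
    params = params or SimParams()
    if seeds is None:
        seeds = session_seeds(base_seed, n_sessions)
    elif len(seeds) != n_sessions:
        raise ValueError("need one seed per session")
    sessions = []
    for i, seed in enumerate(seeds):
        strategy: PassStrategy = (
            "near_target" if i < (n_sessions + 1) // 2 else "near_confederate"
        )
        schedule = build_schedule(plans, seed=seed)
        sessions.append(run_session(schedule, task, params, seed, strategy))
    return sessions
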