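"""Task geometry, coordinate frames, E/A scaling and trial scheduling.

The task space is a 1.50 x 0.89 m tabletop.  An actor standing at a fixed
ready location picks up a disc that appears at one of five pickup locations
to their left and moves it to one of twenty target locations to their right,
either alone or by releasing it for a partner standing across the table.

Two coordinate frames are used throughout the package:

* the *participant frame*, centred on the actor's ready/start hand location,
  with x along the table length (positive to the actor's right) and y along
  the table depth (positive away from the actor); and
* the *table frame*, with the origin at a table corner, spanning
  [0, 1.50] x [0, 0.89] m.

The two differ by a pure translation (the ready location in table
coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Point2",
    "FrameConfig",
    "TaskSpace",
    "TrialSpec",
    "BlockSchedule",
    "SchedulePlans",
    "build_task_space",
    "build_schedule",
    "ea_ratio",
    "to_table_frame",
    "to_participant_frame",
    "TABLE_SIZE",
    "PICKUP_X",
    "TARGET_X",
    "PICKUP_MEAN_Y",
    "PICKUP_EA_LABELS",
    "TARGET_YS",
    "MEAN_REACH",
    "PASS_ANCHOR_NEAR_TARGET",
    "PASS_ANCHOR_NEAR_CONFEDERATE",
]

#: Table dimensions (length, depth) in metres.
TABLE_SIZE: tuple[float, float] = (1.50, 0.89)

#: Pickup column x and the five mean pickup y positions (participant frame, m).
PICKUP_X: float = -0.323
PICKUP_MEAN_Y: tuple[float, ...] = (-0.014, 0.072, 0.158, 0.244, 0.330)

#: Action-scaled labels of the five pickup locations (fractions of reach).
PICKUP_EA_LABELS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)

#: Target column x and the twenty target y positions (participant frame, m).
TARGET_X: float = 1.037
TARGET_YS: tuple[float, ...] = tuple(
    round(-0.07 + 0.035 * k, 10) for k in range(20)
)

#: Mean preferred (comfort) reach distance of the modelled actor, metres.
MEAN_REACH: float = 0.522

#: Empirical release/pass anchor locations, **table frame**, metres.
PASS_ANCHOR_NEAR_TARGET: "Point2"
PASS_ANCHOR_NEAR_CONFEDERATE: "Point2"


class TaskGeometryError(ValueError):
    """Raised when task geometry is inconsistent or out of table bounds."""


@dataclass(frozen=True)
class Point2:
    """A point in the planar task space (metres)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise TaskGeometryError(f"non-finite coordinates: ({self.x}, {self.y})")

    def distance_to(self, other: "Point2") -> float:
        return math.hypot(other.x - self.x, other.y - self.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


PASS_ANCHOR_NEAR_TARGET = Point2(0.7695, 0.5893)
PASS_ANCHOR_NEAR_CONFEDERATE = Point2(0.464, 0.5607)


@dataclass(frozen=True)
class FrameConfig:
    """Placement of the participant frame within the table frame.

    ``ready_table`` is the actor's ready/start hand location expressed in
    table coordinates.  The default (0.35, 0.15) m keeps every pickup and
    target location inside the table with margin; it is configurable because
    the standing position is otherwise unconstrained.
    """

    ready_table: Point2 = field(default_factory=lambda: Point2(0.35, 0.15))
    table_size: tuple[float, float] = TABLE_SIZE

    def __post_init__(self) -> None:
        if not self.contains(self.ready_table):
            raise TaskGeometryError(
                f"ready location {self.ready_table} outside table {self.table_size}"
            )

    def contains(self, p: Point2) -> bool:
        """Whether a table-frame point lies on the table."""
        lx, ly = self.table_size
        return 0.0 <= p.x <= lx and 0.0 <= p.y <= ly


def to_table_frame(p: Point2, frame: FrameConfig) -> Point2:
    """Translate a participant-frame point into table coordinates."""
    return Point2(p.x + frame.ready_table.x, p.y + frame.ready_table.y)


def to_participant_frame(p: Point2, frame: FrameConfig) -> Point2:
    """Translate a table-frame point into participant coordinates."""
    return Point2(p.x - frame.ready_table.x, p.y - frame.ready_table.y)


def ea_ratio(distance: float, reach: float) -> float:
    """Environment/agent action-scaled ratio: ``distance / reach``.

    ``distance`` is the action-relevant environmental extent (here, typically
    a target's y distance or a release point's distance from the actor) and
    ``reach`` the actor's comfortable reach.  This dimensionless ratio is the
    control parameter of the pass/no-pass decision.
    """
    if reach <= 0:
        raise TaskGeometryError(f"reach must be positive, got {reach}")
    if distance < 0:
        raise TaskGeometryError(f"distance must be non-negative, got {distance}")
    return distance / reach


@dataclass(frozen=True)
class TaskSpace:
    """Full geometry of the pick-and-place task (participant frame).

    Exactly five pickup locations (with attached E/A labels 0.2..1.0) and
    twenty target locations; pass anchors are stored in the table frame as
    they are defined relative to the partner's side of the table.
    """

    reach: float
    pickup_locations: tuple[Point2, ...]
    pickup_ea_labels: tuple[float, ...]
    target_locations: tuple[Point2, ...]
    pass_anchor_near_target: Point2
    pass_anchor_near_confederate: Point2
    frame: FrameConfig

    def __post_init__(self) -> None:
        if self.reach <= 0:
            raise TaskGeometryError(f"reach must be positive, got {self.reach}")
        if len(self.pickup_locations) != 5 or len(self.pickup_ea_labels) != 5:
            raise TaskGeometryError("exactly 5 pickup locations/labels required")
        if len(self.target_locations) != 20:
            raise TaskGeometryError("exactly 20 target locations required")
        for p in (*self.pickup_locations, *self.target_locations):
            if not self.frame.contains(to_table_frame(p, self.frame)):
                raise TaskGeometryError(f"grid point {p} escapes table bounds")

    def pickup(self, index: int) -> Point2:
        """Pickup location by 1-based index."""
        return self.pickup_locations[_check_index(index, 5, "pickup")]

    def pickup_label(self, index: int) -> float:
        return self.pickup_ea_labels[_check_index(index, 5, "pickup")]

    def target(self, index: int) -> Point2:
        """Target location by 1-based index (1 = nearest, 20 = farthest)."""
        return self.target_locations[_check_index(index, 20, "target")]

    def target_ea(self, index: int) -> float:
        """E/A ratio of a target: its y distance over the actor's reach.

        Signed: the two targets on the near side of the ready location give
        small negative ratios, which simply drive the decision dynamics
        deeper into the no-pass regime.
        """
        return self.target(index).y / self.reach

    def pass_anchor(self, strategy: str) -> Point2:
        """Pass anchor (participant frame) for a release-location strategy."""
        if strategy == "near_target":
            anchor = self.pass_anchor_near_target
        elif strategy == "near_confederate":
            anchor = self.pass_anchor_near_confederate
        else:
            raise TaskGeometryError(f"unknown pass strategy: {strategy!r}")
        return to_participant_frame(anchor, self.frame)


def _check_index(index: int, n: int, what: str) -> int:
    if not 1 <= index <= n:
        raise TaskGeometryError(f"{what} index {index} out of range 1..{n}")
    return index - 1


def build_task_space(
    reach: float = MEAN_REACH,
    frame: FrameConfig | None = None,
    *,
    scale_pickups_to_reach: bool = False,
) -> TaskSpace:
    """Construct the five-pickup / twenty-target task geometry.

    By default pickup locations use the empirically observed mean positions
    (x = -32.3 cm; y = -1.4 .. 33 cm).  The attached E/A labels
    (0.2, 0.4, 0.6, 0.8, 1.0) — not the Euclidean coordinates — carry the
    action scaling, because the reach calibration was performed from the
    actor's standing position, which is not part of the tabletop geometry.
    With ``scale_pickups_to_reach`` the pickup column is instead spaced in
    strict proportion to ``reach``, anchored so the farthest pickup matches
    the observed farthest position.
    """
    if reach <= 0:
        raise TaskGeometryError(f"reach must be positive, got {reach}")
    frame = frame or FrameConfig()
    if scale_pickups_to_reach:
        y0 = PICKUP_MEAN_Y[-1] - reach  # anchor: label 1.0 at the printed farthest
        pickup_ys = tuple(y0 + lab * reach for lab in PICKUP_EA_LABELS)
    else:
        pickup_ys = PICKUP_MEAN_Y
    pickups = tuple(Point2(PICKUP_X, y) for y in pickup_ys)
    targets = tuple(Point2(TARGET_X, y) for y in TARGET_YS)
    return TaskSpace(
        reach=reach,
        pickup_locations=pickups,
        pickup_ea_labels=PICKUP_EA_LABELS,
        target_locations=targets,
        pass_anchor_near_target=PASS_ANCHOR_NEAR_TARGET,
        pass_anchor_near_confederate=PASS_ANCHOR_NEAR_CONFEDERATE,
        frame=frame,
    )


OrderCondition = Literal["ascending", "descending", "random"]


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the session plan."""

    trial_index: int
    block_index: int
    pickup_index: int
    target_index: int
    order_condition: OrderCondition

    def __post_init__(self) -> None:
        if not 1 <= self.block_index <= 3:
            raise TaskGeometryError(f"block_index {self.block_index} out of range")
        _check_index(self.pickup_index, 5, "pickup")
        _check_index(self.target_index, 20, "target")


@dataclass(frozen=True)
class SchedulePlans:
    """Counterbalancing plans for the ordered blocks."""

    pickup_order_plan: Literal["ascending-first", "descending-first"] = "ascending-first"
    target_order_plan: Literal["asc-desc", "desc-asc"] = "asc-desc"
    block3_reverse_pickups: bool = True


@dataclass(frozen=True)
class BlockSchedule:
    """A 600-trial session plan: ordered / random / ordered blocks of 200."""

    trials: tuple[TrialSpec, ...]
    plans: SchedulePlans
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != 600:
            raise TaskGeometryError(f"expected 600 trials, got {len(self.trials)}")

    def block(self, index: int) -> tuple[TrialSpec, ...]:
        if not 1 <= index <= 3:
            raise TaskGeometryError(f"block index {index} out of range")
        return self.trials[(index - 1) * 200 : index * 200]


def _ordered_block(
    block_index: int,
    trial_start: int,
    pickup_order: Sequence[int],
    target_plan: str,
) -> list[TrialSpec]:
    """One ordered block: 5 pickup runs of 40 trials, each run a 20-target
    ascending sweep and a 20-target descending sweep (order per plan)."""
    asc = list(range(1, 21))
    sweeps = [asc, asc[::-1]] if target_plan == "asc-desc" else [asc[::-1], asc]
    labels = (
        ["ascending", "descending"]
        if target_plan == "asc-desc"
        else ["descending", "ascending"]
    )
    trials: list[TrialSpec] = []
    t = trial_start
    for pk in pickup_order:
        for sweep, label in zip(sweeps, labels):
            for tg in sweep:
                trials.append(TrialSpec(t, block_index, pk, tg, label))
                t += 1
    return trials


def build_schedule(plans: SchedulePlans | None = None, seed: int = 0) -> BlockSchedule:
    """Build the 600-trial session plan.

    Blocks 1 and 3 are ordered: each pickup location is presented in a run of
    40 consecutive trials, within which the 20 targets sweep once ascending
    and once descending.  Block 2 presents every (pickup, target) pair twice
    in a seeded random order (Fisher–Yates shuffle of the 200-pair multiset).
    Every pair therefore occurs exactly 6 times per session.  Deterministic
    for a fixed seed.
    """
    plans = plans or SchedulePlans()
    pickups = list(range(1, 6))
    if plans.pickup_order_plan == "descending-first":
        pickups = pickups[::-1]
    elif plans.pickup_order_plan != "ascending-first":
        raise TaskGeometryError(f"unknown pickup plan {plans.pickup_order_plan!r}")
    if plans.target_order_plan not in ("asc-desc", "desc-asc"):
        raise TaskGeometryError(f"unknown target plan {plans.target_order_plan!r}")

    trials = _ordered_block(1, 1, pickups, plans.target_order_plan)

    pairs = [(pk, tg) for pk in range(1, 6) for tg in range(1, 21)] * 2
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    for i, j in enumerate(order):
        pk, tg = pairs[j]
        trials.append(TrialSpec(201 + i, 2, pk, tg, "random"))

    block3_pickups = pickups[::-1] if plans.block3_reverse_pickups else pickups
    trials += _ordered_block(3, 401, block3_pickups, plans.target_order_plan)
    return BlockSchedule(tuple(trials), plans, seed)


def schedule_to_dataframe(schedule: BlockSchedule, task: TaskSpace):
    """Schedule as a DataFrame with participant-frame coordinates (metres).

    Columns: trial_index, block, order_condition, pickup_index,
    target_index, pickup_x, pickup_y, target_x, target_y.
    """
    import pandas as pd

    rows = []
    for t in schedule.trials:
        pk = task.pickup(t.pickup_index)
        tg = task.target(t.target_index)
        rows.append(
            {
                "trial_index": t.trial_index,
                "block": t.block_index,
                "order_condition": t.order_condition,
                "pickup_index": t.pickup_index,
                "target_index": t.target_index,
                "pickup_x": pk.x,
                "pickup_y": pk.y,
                "target_x": tg.x,
                "target_y": tg.y,
            }
        )
    return pd.DataFrame(rows)
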