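"""Session persistence: trials.csv + trajectories.jsonl + manifest.json.

A session directory holds three files:

* ``manifest.json`` — schema version, seed, pass strategy and the full
  parameter snapshot (a materialised RunConfig), from which the schedule
  and task space are reconstructed exactly;
* ``trials.csv`` — one row per trial (decision, E/A, release location,
  arrival flags, peak speeds);
* ``trajectories.jsonl`` — one JSON record per trajectory sample
  ``{trial, class, t, x, y, heading_deg, speed}``.

``read_session`` rebuilds an equal SessionResult from a complete file set
and raises a descriptive error on a partial one.
"""

from __future__ import annotations

import json
import math
from pathlib import Path


import numpy as np
import pandas as pd

from .config import RunConfig
from .movement import Trajectory
from .simulate import SessionResult, TrialResult
from .task import Point2, build_schedule

__all__ = ["write_session", "read_session", "sessions_equal", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_TRIAL_COLUMNS = [
    "trial_index",
    "block",
    "order_condition",
    "pickup_index",
    "target_index",
    "decision",
    "ea",
    "alpha",
    "decision_x_end",
    "pass_x",
    "pass_y",
    "pickup_arrived",
    "transport_arrived",
    "pickup_peak_speed",
    "transport_peak_speed",
]


def _config_snapshot(session: SessionResult) -> dict:
    """Materialised parameter snapshot sufficient to rebuild the session."""
    p = session.params
    t = session.task
    cfg = RunConfig(
        geometry={
            "reach": t.reach,
            "ready_x": t.frame.ready_table.x,
            "ready_y": t.frame.ready_table.y,
            "table_length": t.frame.table_size[0],
            "table_depth": t.frame.table_size[1],
        },
        schedule={
            "pickup_order_plan": session.schedule.plans.pickup_order_plan,
            "target_order_plan": session.schedule.plans.target_order_plan,
            "block3_reverse_pickups": session.schedule.plans.block3_reverse_pickups,
        },
        steering={
            "b_g": p.steering.b_g,
            "k_g": p.steering.k_g,
            "c1": p.steering.c1,
            "c2": p.steering.c2,
        },
        velocity={
            "b_v": p.velocity["pickup"].b_v,
            "k_v": p.velocity["pickup"].k_v,
            "C_v_pickup": p.velocity["pickup"].C_v,
            "C_v_pass": p.velocity["pass"].C_v,
            "C_v_target": p.velocity["target"].C_v,
        },
        decision={
            "sigma": p.decision.sigma,
            "delta": p.decision.delta,
            "affordance_distance_mode": p.decision.affordance_distance_mode,
            "carry_across_blocks": p.carry_across_blocks,
        },
        angles={
            "pickup_endpoints_deg": p.angles.pickup_endpoints_deg,
            "pass_endpoints_deg": p.angles.pass_endpoints_deg,
            "target_endpoints_deg": p.angles.target_endpoints_deg,
            "saturation_rate": p.angles.saturation_rate,
            "noise_halfwidth_deg": p.angles.noise_halfwidth_deg,
        },
        jitter={"log_mu": p.jitter.log_mu, "log_sigma": p.jitter.log_sigma},
        integration={
            "dt": p.integration.dt,
            "stop_radius": p.integration.stop_radius,
            "max_steps": p.integration.max_steps,
            "heading_noise_deg": p.integration.heading_noise_deg,
            "decision_steps": p.integration.decision_steps,
            "decision_dt": p.integration.decision_dt,
        },
        seed=session.seed,
        pass_strategy=session.pass_strategy,
    )
    return cfg.model_dump(mode="json")


def write_session(session: SessionResult, directory: str | Path) -> Path:
    """Write a session to a directory; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": session.seed,
        "schedule_seed": session.schedule.seed,
        "pass_strategy": session.pass_strategy,
        "n_trials": len(session.trials),
        "config": _config_snapshot(session),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    rows = []
    for tr in session.trials:
        rows.append(
            {
                "trial_index": tr.spec.trial_index,
                "block": tr.spec.block_index,
                "order_condition": tr.spec.order_condition,
                "pickup_index": tr.spec.pickup_index,
                "target_index": tr.spec.target_index,
                "decision": tr.decision,
                "ea": repr(tr.ea_used),
                "alpha": repr(tr.alpha),
                "decision_x_end": repr(tr.decision_x_end),
                "pass_x": "" if tr.pass_location is None else repr(tr.pass_location.x),
                "pass_y": "" if tr.pass_location is None else repr(tr.pass_location.y),
                "pickup_arrived": tr.pickup_trajectory.arrived,
                "transport_arrived": tr.transport_trajectory.arrived,
                "pickup_peak_speed": repr(tr.pickup_trajectory.peak_speed),
                "transport_peak_speed": repr(tr.transport_trajectory.peak_speed),
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
        directory / "trials.csv", index=False
    )

    with open(directory / "trajectories.jsonl", "w") as fh:
        for tr in session.trials:
            for traj, which in (
                (tr.pickup_trajectory, "pickup"),
                (tr.transport_trajectory, tr.transport_trajectory.movement_class),
            ):
                for k in range(len(traj)):
                    rec = {
                        "trial": tr.spec.trial_index,
                        "class": which,
                        "t": traj.t[k],
                        "x": traj.x[k],
                        "y": traj.y[k],
                        "heading_deg": math.degrees(traj.heading[k]),
                        "speed": traj.speed[k],
                    }
                    fh.write(json.dumps(rec) + "\n")
    return directory


def _read_trajectories(path: Path) -> dict[tuple[int, str], dict[str, list[float]]]:
    out: dict[tuple[int, str], dict[str, list[float]]] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            key = (rec["trial"], rec["class"])
            buf = out.setdefault(
                key, {"t": [], "x": [], "y": [], "heading": [], "speed": []}
            )
            buf["t"].append(rec["t"])
            buf["x"].append(rec["x"])
            buf["y"].append(rec["y"])
            buf["heading"].append(math.radians(rec["heading_deg"]))
            buf["speed"].append(rec["speed"])
    return out


def read_session(directory: str | Path) -> SessionResult:
    """Reconstruct a SessionResult from a session directory."""
    directory = Path(directory)
    for name in ("manifest.json", "trials.csv", "trajectories.jsonl"):
        if not (directory / name).exists():
            raise FileNotFoundError(
                f"incomplete session directory {directory}: missing {name}"
            )
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {manifest.get('schema_version')!r}"
        )
    cfg = RunConfig(**manifest["config"])
    task = cfg.task_space()
    params = cfg.sim_params()
    schedule = build_schedule(cfg.schedule_plans(), seed=manifest["schedule_seed"])

    df = pd.read_csv(directory / "trials.csv", float_precision="round_trip")
    trajs = _read_trajectories(directory / "trajectories.jsonl")

    trials: list[TrialResult] = []
    for spec, row in zip(schedule.trials, df.itertuples(index=False)):
        if spec.trial_index != row.trial_index:
            raise ValueError(
                f"trials.csv out of order at trial {row.trial_index}"
            )
        decision = row.decision
        transport_class = "pass" if decision == "pass" else "target"

        def build(which: str, arrived: bool) -> Trajectory:
            try:
                buf = trajs[(spec.trial_index, which)]
            except KeyError:
                raise ValueError(
                    f"missing {which!r} trajectory for trial {spec.trial_index}"
                )
            goal = (
                task.pickup(spec.pickup_index)
                if which == "pickup"
                else (
                    Point2(float(row.pass_x), float(row.pass_y))
                    if which == "pass"
                    else task.target(spec.target_index)
                )
            )
            return Trajectory(
                t=np.asarray(buf["t"]),
                x=np.asarray(buf["x"]),
                y=np.asarray(buf["y"]),
                heading=np.asarray(buf["heading"]),
                speed=np.asarray(buf["speed"]),
                goal=goal,
                movement_class=which,  # type: ignore[arg-type]
                arrived=bool(arrived),
                dt=params.integration.dt,
            )

        trials.append(
            TrialResult(
                spec=spec,
                decision=decision,
                ea_used=float(row.ea),
                alpha=float(row.alpha),
                decision_x_end=float(row.decision_x_end),
                pass_location=(
                    Point2(float(row.pass_x), float(row.pass_y))
                    if decision == "pass"
                    else None
                ),
                pickup_trajectory=build("pickup", row.pickup_arrived),
                transport_trajectory=build(transport_class, row.transport_arrived),
            )
        )
    return SessionResult(
        schedule=schedule,
        trials=trials,
        pass_strategy=manifest["pass_strategy"],
        seed=manifest["seed"],
        task=task,
        params=params,
    )


def sessions_equal(a: SessionResult, b: SessionResult) -> bool:
    """Whether two sessions agree on every decision, location and sample.

    Positions, times, speeds and scalar outcomes must match exactly
    (JSON round-trips preserve float64); headings to float tolerance
    (stored in degrees).
    """
    if (
        a.seed != b.seed
        or a.pass_strategy != b.pass_strategy
        or len(a.trials) != len(b.trials)
    ):
        return False
    for ta, tb in zip(a.trials, b.trials):
        if ta.spec != tb.spec or ta.decision != tb.decision:
            return False
        if (ta.ea_used, ta.alpha, ta.decision_x_end) != (
            tb.ea_used,
            tb.alpha,
            tb.decision_x_end,
        ):
            return False
        if (ta.pass_location is None) != (tb.pass_location is None):
            return False
        if ta.pass_location is not None and ta.pass_location != tb.pass_location:
            return False
        for x, y in (
            (ta.pickup_trajectory, tb.pickup_trajectory),
            (ta.transport_trajectory, tb.transport_trajectory),
        ):
            if x.arrived != y.arrived or len(x) != len(y):
                return False
            if not (
                np.array_equal(x.t, y.t)
                and np.array_equal(x.x, y.x)
                and np.array_equal(x.y, y.y)
                and np.array_equal(x.speed, y.speed)
                and np.allclose(x.heading, y.heading, atol=1e-12)
            ):
                return False
    return True
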