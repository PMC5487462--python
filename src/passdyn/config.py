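"""Run configuration: a validated, self-contained parameter snapshot.

``RunConfig`` is the single serialisable description of a simulation run:
geometry, schedule plans, model parameters, noise settings and seeds.  It
validates on load (unknown keys are rejected, positivity constraints are
enforced) and materialises every default, so a saved config or manifest
fully reproduces its run.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .decision import DEFAULT_DELTA, DEFAULT_SIGMA, DecisionParams
from .movement import SteeringParams, VelocityParams
from .simulate import (
    CALIBRATED_CV,
    InitialAngleModel,
    IntegrationSettings,
    PassJitter,
    SimParams,
)
from .task import FrameConfig, Point2, SchedulePlans, TaskSpace, build_task_space

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryConfig(_Strict):
    reach: float = Field(default=0.522, gt=0)
    ready_x: float = 0.35
    ready_y: float = 0.15
    table_length: float = Field(default=1.50, gt=0)
    table_depth: float = Field(default=0.89, gt=0)
    scale_pickups_to_reach: bool = False


class ScheduleConfig(_Strict):
    pickup_order_plan: Literal["ascending-first", "descending-first"] = "ascending-first"
    target_order_plan: Literal["asc-desc", "desc-asc"] = "asc-desc"
    block3_reverse_pickups: bool = True


class SteeringConfig(_Strict):
    b_g: float = Field(default=16.0, gt=0)
    k_g: float = Field(default=60.0, gt=0)
    c1: float = Field(default=0.4, gt=0)
    c2: float = Field(default=0.4, gt=0)


class VelocityConfig(_Strict):
    b_v: float = Field(default=48.0, gt=0)
    k_v: float = Field(default=576.0, gt=0)
    C_v_pickup: float = Field(default=CALIBRATED_CV["pickup"], gt=0)
    C_v_pass: float = Field(default=CALIBRATED_CV["pass"], gt=0)
    C_v_target: float = Field(default=CALIBRATED_CV["target"], gt=0)


class DecisionConfig(_Strict):
    sigma: float = DEFAULT_SIGMA
    delta: float = Field(default=DEFAULT_DELTA, gt=0)
    affordance_distance_mode: Literal[
        "target_y_over_reach", "euclidean_hand_target"
    ] = "target_y_over_reach"
    carry_across_blocks: bool = True


class AnglesConfig(_Strict):
    pickup_endpoints_deg: tuple[float, float] = (185.88, 201.59)
    pass_endpoints_deg: tuple[float, float] = (31.21, -35.15)
    target_endpoints_deg: tuple[float, float] = (31.35, -33.89)
    saturation_rate: float = Field(default=2.0, gt=0)
    noise_halfwidth_deg: float = Field(default=20.0, ge=0)


class JitterConfig(_Strict):
    log_mu: float = math.log(0.05)
    log_sigma: float = Field(default=0.5, ge=0)


class IntegrationConfig(_Strict):
    dt: float = Field(default=0.01, gt=0)
    stop_radius: float = Field(default=0.04, gt=0)
    max_steps: int = Field(default=5000, gt=0)
    heading_noise_deg: float = Field(default=1.14, ge=0)
    decision_steps: int = Field(default=1500, ge=1)
    decision_dt: float = Field(default=0.005, gt=0)


class RunConfig(_Strict):
    """Validated, fully materialised simulation configuration."""

    geometry: GeometryConfig = GeometryConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    steering: SteeringConfig = SteeringConfig()
    velocity: VelocityConfig = VelocityConfig()
    decision: DecisionConfig = DecisionConfig()
    angles: AnglesConfig = AnglesConfig()
    jitter: JitterConfig = JitterConfig()
    integration: IntegrationConfig = IntegrationConfig()
    seed: int = 0
    pass_strategy: Literal["near_target", "near_confederate"] = "near_target"
    n_sessions: int = Field(default=1, ge=1)

    def task_space(self) -> TaskSpace:
        frame = FrameConfig(
            ready_table=Point2(self.geometry.ready_x, self.geometry.ready_y),
            table_size=(self.geometry.table_length, self.geometry.table_depth),
        )
        return build_task_space(
            self.geometry.reach,
            frame,
            scale_pickups_to_reach=self.geometry.scale_pickups_to_reach,
        )

    def schedule_plans(self) -> SchedulePlans:
        return SchedulePlans(
            pickup_order_plan=self.schedule.pickup_order_plan,
            target_order_plan=self.schedule.target_order_plan,
            block3_reverse_pickups=self.schedule.block3_reverse_pickups,
        )

    def sim_params(self) -> SimParams:
        v = self.velocity
        return SimParams(
            steering=SteeringParams(
                b_g=self.steering.b_g,
                k_g=self.steering.k_g,
                c1=self.steering.c1,
                c2=self.steering.c2,
            ),
            velocity={
                "pickup": VelocityParams(v.b_v, v.k_v, v.C_v_pickup),
                "pass": VelocityParams(v.b_v, v.k_v, v.C_v_pass),
                "target": VelocityParams(v.b_v, v.k_v, v.C_v_target),
            },
            decision=DecisionParams(
                sigma=self.decision.sigma,
                delta=self.decision.delta,
                affordance_distance_mode=self.decision.affordance_distance_mode,
            ),
            angles=InitialAngleModel(
                pickup_endpoints_deg=self.angles.pickup_endpoints_deg,
                pass_endpoints_deg=self.angles.pass_endpoints_deg,
                target_endpoints_deg=self.angles.target_endpoints_deg,
                saturation_rate=self.angles.saturation_rate,
                noise_halfwidth_deg=self.angles.noise_halfwidth_deg,
            ),
            jitter=PassJitter(
                log_mu=self.jitter.log_mu, log_sigma=self.jitter.log_sigma
            ),
            integration=IntegrationSettings(
                dt=self.integration.dt,
                stop_radius=self.integration.stop_radius,
                max_steps=self.integration.max_steps,
                heading_noise_deg=self.integration.heading_noise_deg,
                decision_steps=self.integration.decision_steps,
                decision_dt=self.integration.decision_dt,
            ),
            carry_across_blocks=self.decision.carry_across_blocks,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; empty files give all defaults.

    Unknown keys and constraint violations raise ``pydantic.ValidationError``
    naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a fully materialised config as YAML (round-trips via load)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
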