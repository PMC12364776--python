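"""Run configuration: a validated YAML schema covering phantom, beam, plan,
optimizer and scenario settings, with the study defaults baked in."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .phantom import PhantomSpec, TARGET_NAMES
from .plans import PlanSettings


class PhantomConfig(BaseModel):
    spacing: float = Field(0.25, gt=0.0, le=1.0, description="voxel pitch, cm")
    target: Literal["CTV_small", "CTV_4.5H", "CTV_6H"] = "CTV_small"
    asymmetric: bool = False

    def spec(self) -> PhantomSpec:
        return PhantomSpec(asymmetric=self.asymmetric)


class PlanConfig(BaseModel):
    n_directions: int = Field(20, ge=1)
    angles: Optional[list[float]] = None  # explicit beams (e.g. 3-beam IMPT)
    shoot_through: bool = True
    collimated: bool = False
    margin_factor: Optional[float] = None  # default 1.0 / 1.25 (uncoll/coll)
    spot_spacing: float = Field(0.6, gt=0.0)
    layers_initial: int = Field(480, ge=1)
    layers_final: int = Field(240, ge=1)
    prescription: float = Field(60.0, gt=0.0)
    fractions: int = Field(30, ge=1)
    falloff_weight_factor: float = Field(1.0, ge=0.0)
    robust: bool = False

    def settings(self) -> PlanSettings:
        return PlanSettings(
            n_directions=self.n_directions,
            angles=None if self.angles is None else list(self.angles),
            shoot_through=self.shoot_through,
            collimated=self.collimated,
            margin_factor=self.margin_factor,
            spot_spacing=self.spot_spacing,
            layers_initial=self.layers_initial,
            layers_final=self.layers_final,
            prescription=self.prescription,
            fractions=self.fractions,
        )


class OptimizerConfig(BaseModel):
    maxiter: int = Field(200, ge=1)
    tol: float = Field(1e-6, gt=0.0)
    seed: int = 17


class ScenarioConfig(BaseModel):
    kind: Literal["spr_scale", "setup_shift", "displace_shoulder"] = "spr_scale"
    spr_scale: float = Field(1.05, gt=0.0)
    shift_cm: list[float] = [0.0, 0.5, 0.0]
    displacement_cm: list[float] = [0.0, 2.0, 0.0]


class RunConfig(BaseModel):
    phantom: PhantomConfig = PhantomConfig()
    plan: PlanConfig = PlanConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    output_dir: str = "arcst_out"


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        raise ValueError(f"invalid configuration {path}:\n{e}") from e


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
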