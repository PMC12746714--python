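"""Validated experiment configuration (YAML in, pydantic schema check).

A stored configuration plus a seed fully determines every artifact the CLI
writes, so any table or model file can be regenerated bit-identically from
its manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError  # noqa: F401


class PickPlaceBlock(BaseModel):
    n_reps: int = Field(10, ge=0)
    noise_scale: float = Field(0.02, ge=0)


class TPCBlock(BaseModel):
    n_hidden: int = Field(256, ge=1)
    epochs: int = Field(200, ge=0)
    weight_lr: float = Field(1e-4, gt=0)
    inference_lr: float = Field(1e-2, gt=0)
    inference_iters: int = Field(100, ge=1)
    activation: Literal["tanh", "linear"] = "tanh"


class FaultGridBlock(BaseModel):
    percentile: float = Field(95.0, gt=0, le=100)
    joints: list[int] = Field(default_factory=lambda: list(range(1, 8)))
    fault_times: list[float] = Field(default_factory=lambda: [1.0 + 0.5 * i for i in range(11)])
    overshoots: list[float] = Field(default_factory=lambda: [-15.0, -10.0, -5.0, 5.0, 10.0, 15.0])


class FollowThroughBlock(BaseModel):
    conditions: list[Literal["planning_only", "planning_and_execution", "execution_only"]] = Field(
        default_factory=lambda: ["planning_only", "planning_and_execution", "execution_only"]
    )
    n_trials: int = Field(4, ge=2)
    n_recall: int = Field(12, ge=1)
    noise_scale: float = Field(0.02, ge=0)
    amplitude: float = Field(0.02, gt=0)
    tpc_hidden: int = Field(128, ge=1)
    tpc_epochs: int = Field(600, ge=0)
    rnn_hidden: int = Field(64, ge=1)
    rnn_iters: int = Field(1200, ge=0)
    rnn_lr: float = Field(5e-3, gt=0)
    rnn_optimizer: Literal["sgd", "adam"] = "adam"
    iteration_grid: list[int] = Field(default_factory=lambda: [2, 5, 10, 20, 50, 100])


class ExperimentConfig(BaseModel):
    """Top-level configuration for every CLI subcommand."""

    task: Literal["faults", "followthrough", "speed_accuracy"] = "faults"
    seeds: list[int] = Field(default_factory=lambda: [0])
    pick_place: PickPlaceBlock = Field(default_factory=PickPlaceBlock)
    tpc: TPCBlock = Field(default_factory=TPCBlock)
    fault_grid: FaultGridBlock = Field(default_factory=FaultGridBlock)
    followthrough: FollowThroughBlock = Field(default_factory=FollowThroughBlock)

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "ExperimentConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
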