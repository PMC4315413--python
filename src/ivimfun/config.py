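"""Validated run configuration for the command-line workflow.

A single YAML file drives every stage; unknown keys are rejected so typos
fail loudly before any computation starts.  All randomness flows from the
single ``seed``: stages derive their own deterministic sub-seeds, so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PhantomOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int] = (64, 64)
    brain_radius: float = 28.0
    gm_ribbon_width: float = 7.0
    visual_extent: float = 12.0
    n_subjects: int = Field(8, ge=1)
    blocks_per_condition: int = Field(5, ge=1)
    sd_scale: float = Field(1.0, ge=0)
    snr_b0: float = Field(107.4, gt=0)
    snr_bmax: float = Field(34.2, gt=0)


class FittingOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    b_threshold: float = Field(200.0, ge=0)
    dstar_max: float = Field(0.1, gt=0)


class SimulationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    snr_values: list[float] = [10, 25, 50, 100, 200, 400]
    n_replicates: int = Field(10_000, ge=1)
    f_grid: list[float] | None = None
    dstar_grid: list[float] | None = None


class AnalysisOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_threshold: float = 5.0
    prob_floor: float = Field(0.5, ge=0, le=1)
    direction: str = "increase"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    verbosity: int = 1
    phantom: PhantomOptions = PhantomOptions()
    fitting: FittingOptions = FittingOptions()
    simulation: SimulationOptions = SimulationOptions()
    analysis: AnalysisOptions = AnalysisOptions()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a config, for run logs."""
    blob = yaml.safe_dump(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(config: RunConfig, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
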