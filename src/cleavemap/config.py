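"""Typed pipeline configuration (JSON-loadable, fully captured in run reports)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .peptides import AMINO_ACIDS

__all__ = [
    "ModelConfig",
    "SimulateConfig",
    "PanelConfig",
    "AlignConfig",
    "ProfileConfig",
    "PipelineConfig",
    "load_config",
]


class ModelConfig(BaseModel):
    """Planted specificity model: which P1 residues are cleaved and how hard."""

    p1_residues: str = "FYW"
    p1_weights: list[float] | None = None
    p2prime_acidic_mass: float | None = None
    background_release: float = Field(0.03, ge=0.0, lt=1.0)
    saturation: float = Field(4.0, gt=0.0)

    @field_validator("p1_residues")
    @classmethod
    def _check_residues(cls, v: str) -> str:
        bad = sorted(set(v) - set(AMINO_ACIDS))
        if bad:
            raise ValueError(f"non-standard P1 residues: {bad}")
        if not v:
            raise ValueError("p1_residues must not be empty")
        return v


class SimulateConfig(BaseModel):
    """Library and biopanning scale; defaults mirror the bench campaign shape."""

    library_size: int = Field(100_000, ge=1)
    rounds: int = Field(5, ge=1)
    carryover: int = Field(100_000, ge=1)
    sample_size: int = Field(96, ge=1)


class PanelConfig(BaseModel):
    """Chromogenic panel simulation and analysis parameters."""

    times_min: list[float] = [0, 15, 30, 45, 60, 90, 120, 180, 240, 300, 360]
    noise_sd: float = Field(0.005, ge=0.0)
    k_max: float = Field(0.02, gt=0.0)
    threshold: float = Field(0.2, gt=0.0, lt=1.0)
    window_fraction: float = Field(0.2, gt=0.0, le=1.0)


class AlignConfig(BaseModel):
    """Anchored-alignment parameters."""

    p1_set: str | None = None  # override the panel-called candidate set
    pseudocount: float = Field(0.5, ge=0.0)
    arm_policy: str = "mask"
    weighting: str = "by_multiplicity"
    tie_rule: str = "nterminal"
    max_iter: int = Field(50, ge=1)
    frame_p: int = Field(5, ge=1)
    frame_prime: int = Field(4, ge=1)


class ProfileConfig(BaseModel):
    """Reporting parameters (narrower report frame, consensus threshold)."""

    report_p: int = Field(4, ge=1)
    report_prime: int = Field(4, ge=1)
    major_threshold: float = Field(0.5, gt=0.0, le=1.0)
    render_png: bool = False


class PipelineConfig(BaseModel):
    """End-to-end run: simulate -> panel -> align -> profile -> compare."""

    seed: int
    outdir: str
    model: ModelConfig = ModelConfig()
    simulate: SimulateConfig = SimulateConfig()
    panel: PanelConfig = PanelConfig()
    align: AlignConfig = AlignConfig()
    profile: ProfileConfig = ProfileConfig()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))
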