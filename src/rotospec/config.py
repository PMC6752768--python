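"""Validated run configuration (TOML or JSON) for the pipeline driver."""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

from .parameters import DOUBLE_SHELL_FREE

__all__ = ["MediumConfig", "FieldSettings", "FitSettings", "BoundsOverride",
           "CohortSettings", "RunConfig", "load_config"]

# physically admissible envelopes for bound overrides
_PHYSICAL_RANGES = {
    "eps_mb": (1.0, 1e3), "sigma_mb": (0.0, 1e2), "eps_cp": (1.0, 1e3),
    "sigma_cp": (0.0, 1e2), "t": (0.0, 1e-6),
    "eps_nb": (1.0, 1e3), "sigma_nb": (0.0, 1e2), "eps_np": (1.0, 1e3),
    "sigma_np": (0.0, 1e2), "t_n": (0.0, 1e-6),
}


class MediumConfig(BaseModel):
    rel_permittivity: float = Field(80.0, gt=0)
    conductivity_S_per_m: float = Field(0.01, ge=0)
    viscosity_Pa_s: float = Field(0.89e-3, gt=0)


class FieldSettings(BaseModel):
    e_rms_V_per_m: float = Field(14e3, gt=0)
    f_min_hz: float = Field(3e3, gt=0)
    f_max_hz: float = Field(10e6, gt=0)
    n_points: int = Field(20, ge=5)

    @model_validator(mode="after")
    def _ordered(self):
        if self.f_min_hz >= self.f_max_hz:
            raise ValueError("f_min_hz must be < f_max_hz")
        return self


class FitSettings(BaseModel):
    model: Literal["single", "double", "both"] = "single"
    method: Literal["lm", "mcmc", "both"] = "lm"
    n_restarts: int = Field(4, ge=0)
    n_walkers: int = Field(20, ge=4)
    n_temps: int = Field(5, ge=1)
    n_steps: int = Field(10000, ge=1)
    temp_ratio: float = Field(2.0, gt=1)


class BoundsOverride(BaseModel):
    name: str
    lower: float
    upper: float

    @model_validator(mode="after")
    def _check(self):
        if self.name not in DOUBLE_SHELL_FREE:
            raise ValueError(f"unknown parameter {self.name!r}")
        lo, hi = _PHYSICAL_RANGES[self.name]
        if not (lo <= self.lower < self.upper <= hi):
            raise ValueError(
                f"bounds for {self.name} must satisfy "
                f"{lo} <= lower < upper <= {hi}")
        return self


class CohortSettings(BaseModel):
    label: str
    n_cells: int = Field(ge=1)
    radius_mean_m: float = Field(gt=0)
    radius_sd_m: float = Field(ge=0)
    nucleus_ratio: float = Field(0.65, gt=0, lt=1)
    param_means: dict[str, float] = Field(default_factory=dict)
    param_sds: dict[str, float] = Field(default_factory=dict)
    noise_sd_fraction: float = Field(0.05, ge=0)


class RunConfig(BaseModel):
    """Full pipeline configuration; defaults reproduce the bundled demo."""

    seed: int = 0
    out_dir: str = "rotospec-out"
    medium: MediumConfig = MediumConfig()
    field: FieldSettings = FieldSettings()
    fit: FitSettings = FitSettings()
    bounds: list[BoundsOverride] = Field(default_factory=list)
    cohorts: list[CohortSettings] = Field(default_factory=list)  # [] => presets
    moving_average_window: int = Field(5, ge=1)

    @field_validator("moving_average_window")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("moving_average_window must be odd")
        return v

    def config_hash(self) -> str:
        """Stable hash of the scientific settings (output paths excluded)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        dump = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(dump.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a TOML (default) or JSON run configuration."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text)
    return RunConfig.model_validate(data)
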