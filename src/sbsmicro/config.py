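"""Run configuration: a validated, serializable description of a pipeline run.

The schema is published programmatically (``RunConfig.model_json_schema()``)
and configs load from YAML or JSON.  All physical quantities carry their
units in the field names (GHz, µm, ms, MHz).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .synth import FrequencyAxis, ScanGeometry

__all__ = [
    "AxisConfig",
    "PulseConfig",
    "GeometryConfig",
    "FitOptions",
    "ClassifyOptions",
    "RunConfig",
    "load_config",
]


class AxisConfig(BaseModel):
    start_ghz: float = 4.0
    end_ghz: float = 6.0
    n_points: int = Field(default=100, ge=3)

    @model_validator(mode="after")
    def _check(self) -> "AxisConfig":
        if self.end_ghz <= self.start_ghz:
            raise ValueError("end_ghz must exceed start_ghz")
        return self

    def build(self) -> FrequencyAxis:
        return FrequencyAxis(self.start_ghz, self.end_ghz, self.n_points)


class PulseConfig(BaseModel):
    pulse_width_ns: float = Field(default=40.0, gt=0)
    rep_rate_mhz: float = Field(default=1.1, gt=0)
    avg_pump_mw: float = Field(default=13.0, ge=0)
    avg_probe_mw: float = Field(default=5.0, ge=0)


class GeometryConfig(BaseModel):
    nx: int = Field(default=16, ge=1)
    ny: int = Field(default=16, ge=1)
    nz: int = Field(default=1, ge=1)
    step_x_um: float = Field(default=0.25, gt=0)
    step_y_um: float = Field(default=0.25, gt=0)
    step_z_um: float = Field(default=1.0, gt=0)
    pixel_time_ms: float = Field(default=20.0, gt=0)
    n_freq: int = Field(default=100, ge=3)
    serpentine: bool = True
    z_flip: bool = True
    stage_delay_ms: float = Field(default=0.0, ge=0)

    def build(self) -> ScanGeometry:
        return ScanGeometry(
            nx=self.nx, ny=self.ny, nz=self.nz,
            step_x_um=self.step_x_um, step_y_um=self.step_y_um,
            step_z_um=self.step_z_um, pixel_time_ms=self.pixel_time_ms,
            n_freq=self.n_freq, serpentine=self.serpentine,
            z_flip=self.z_flip, stage_delay_ms=self.stage_delay_ms,
        )


class FitOptions(BaseModel):
    n_peaks: int = Field(default=1, ge=1, le=3)
    noise_window_ghz: Optional[tuple[float, float]] = None
    filter_cutoff_hz: float = Field(default=50.0, gt=0)
    dc_level: float = Field(default=100.0, gt=0)


class ClassifyOptions(BaseModel):
    offset_min: float = -0.5
    offset_max: float = 0.5
    n_offsets: int = Field(default=21, ge=3)
    min_fwhm_ghz: float = Field(default=0.15, ge=0)
    significance: float = Field(default=4.0, ge=0)


class RunConfig(BaseModel):
    """Top-level configuration binding all pipeline stages."""

    axis: AxisConfig = AxisConfig()
    pulse: PulseConfig = PulseConfig()
    geometry: GeometryConfig = GeometryConfig()
    fit: FitOptions = FitOptions()
    classify: ClassifyOptions = ClassifyOptions()
    phantom: Literal["water", "bead_in_agarose", "oil_glass_edge", "two_layer"] = "water"
    snr: float = Field(default=38.0, gt=0)
    seed: int = 0
    output_dir: str = "sbsmicro_out"

    def config_hash(self) -> str:
        """Stable sha256 of the resolved configuration (for run logs)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file, applying keyword overrides on top."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    return RunConfig.model_validate(data)
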