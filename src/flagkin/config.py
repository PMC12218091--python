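"""Declarative run configuration (YAML) and provenance helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .core import SectionBoundaries
from .energetics import MaterialParams
from .trace import TraceConfig

__all__ = ["RunConfig", "load_config", "config_hash", "provenance"]


class SimulateSection(BaseModel):
    n_cells: int = 10
    weights: tuple[float, float, float, float] = (0.17, 0.60, 0.19, 0.04)
    seed: int = 0
    fps: float = 250.0
    duration: float = 4.0
    total_length: float = 110.0
    wavelength: float = 110.0
    snr: float = 10.0
    pixel_size: float = 0.33
    psf_sigma: float = 0.6
    phase_jitter_stiff: float = 0.0


class TraceSection(BaseModel):
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    min_object_px: int = 30
    head_anchor: tuple[float, float] = (0.0, 0.0)
    head_mask_radius: float = 0.0
    spline_smoothing: float = 0.02
    resample_ds: float = 1.0
    max_length: float = 100.0
    prune_length: float = 3.0
    min_traced_fraction: float = 0.8
    refine_normal: bool = True
    refine_halfwidth: float = 1.5
    anchor_clamp: bool = True
    anchor_clamp_max: float = 5.0

    def to_trace_config(self) -> TraceConfig:
        return TraceConfig(**self.model_dump())


class KinematicsSection(BaseModel):
    head_len: float = 6.3
    mid_len: float = 22.4
    principal_len: float = 80.0
    amplitude_smooth_window: int = 1

    def to_bounds(self) -> SectionBoundaries:
        return SectionBoundaries(self.head_len, self.mid_len, self.principal_len)


class EnergeticsSection(BaseModel):
    EI: float = 2e-21
    eta_i: float = 1e-22
    xi_t: float = 0.7e-3
    xi_n: float = 1.4e-3
    a: float = 1.85e-7
    smooth_window: int = 5

    def to_material(self) -> MaterialParams:
        return MaterialParams(EI=self.EI, eta_i=self.eta_i,
                              xi_t=self.xi_t, xi_n=self.xi_n, a=self.a)


class StatsSection(BaseModel):
    welch: bool = False
    quantities: list[str] = Field(
        default_factory=lambda: ["beat_frequency", "amplitude_principal",
                                 "p_in_fw", "d_m_fw", "d_i_fw", "d_h_fw",
                                 "d_h_mid_fw", "d_h_principal_fw"]
    )


class RunConfig(BaseModel):
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    trace: TraceSection = Field(default_factory=TraceSection)
    kinematics: KinematicsSection = Field(default_factory=KinematicsSection)
    energetics: EnergeticsSection = Field(default_factory=EnergeticsSection)
    stats: StatsSection = Field(default_factory=StatsSection)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance(cfg: RunConfig, seed: int | None = None) -> dict:
    from . import __version__

    return {"package": "flagkin", "version": __version__,
            "config_hash": config_hash(cfg), "seed": seed}
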