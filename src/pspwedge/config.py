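"""Run configuration: schema, defaults, loading, and hashing.

All tunable quantities — phantom geometry, the two system profiles,
factor levels, repeat count, noise and seeding, ROI margin, the
significance level and the fixed Box-Cox powers — live in one YAML
document validated against a strict schema (unknown keys rejected).
The packaged default configuration encodes the study conditions.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError
from .geometry import PhantomGeometry, build_geometry
from .systems import SystemProfile

__all__ = [
    "GeometryConfig",
    "SystemConfig",
    "RunConfig",
    "default_config",
    "load_config",
    "config_hash",
    "build_profiles",
    "geometry_from_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    rows: int = 300
    cols: int = 540
    wedge_row_start: int = 15
    step_height_px: int = 30
    wedge_col_start: int = 30
    wedge_col_stop: int = 510
    n_steps: int = 9
    thickness_increment_mm: float = 1.0


class SystemConfig(_StrictModel):
    mu_al_per_mm: float
    dap_rate_mgycm2_per_s: float
    response_gain_gv_per_decade: float
    response_offset_gv: float
    signal_floor: float
    noise_sigma_gv: float
    fade_tau_s: float


class RunConfig(_StrictModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    systems: dict[str, SystemConfig]
    exposure_times_s: list[float]
    light_durations_s: list[float]
    n_repeats: int = 10
    noise_enabled: bool = True
    root_seed: int = 20221109
    roi_margin_px: int = 4
    alpha: float = 0.05
    boxcox_lambda: dict[str, dict[str, float]] = Field(default_factory=dict)
    tube: dict[str, float] = Field(default_factory=dict)
    output_dir: str | None = None

    @field_validator("exposure_times_s")
    @classmethod
    def _exposures_valid(cls, v):
        if any(t <= 0 for t in v):
            raise ValueError("exposure times must be positive")
        if sorted(set(v)) != v:
            raise ValueError("exposure times must be strictly increasing")
        return v

    @field_validator("light_durations_s")
    @classmethod
    def _lights_valid(cls, v):
        if any(t < 0 for t in v):
            raise ValueError("light durations must be >= 0")
        if sorted(set(v)) != v:
            raise ValueError("light durations must be strictly increasing")
        return v

    @field_validator("n_repeats")
    @classmethod
    def _repeats_valid(cls, v):
        if v < 1:
            raise ValueError("n_repeats must be >= 1")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_valid(cls, v):
        if not 0 < v < 1:
            raise ValueError("alpha must be in (0, 1)")
        return v


def default_config() -> RunConfig:
    """The packaged default configuration (the study conditions)."""
    text = resources.files("pspwedge").joinpath("data/default_config.yaml") \
        .read_text(encoding="utf-8")
    return _from_mapping(yaml.safe_load(text))


def _from_mapping(mapping: dict) -> RunConfig:
    try:
        return RunConfig(**mapping)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives the default."""
    if path is None:
        return default_config()
    try:
        mapping = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable YAML: {exc}") from exc
    if not isinstance(mapping, dict):
        raise ConfigError("config file must contain a mapping")
    return _from_mapping(mapping)


def config_hash(config: RunConfig) -> str:
    """Stable fingerprint of a configuration (first 12 hex digits of the
    SHA-256 of its canonical JSON dump)."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


def build_profiles(config: RunConfig) -> dict[str, SystemProfile]:
    """Materialise :class:`SystemProfile` objects from the config."""
    out = {}
    for name, sc in config.systems.items():
        try:
            out[name] = SystemProfile(
                name=name,
                mu_al_per_mm=sc.mu_al_per_mm,
                dap_rate=sc.dap_rate_mgycm2_per_s,
                response_gain=sc.response_gain_gv_per_decade,
                response_offset=sc.response_offset_gv,
                signal_floor=sc.signal_floor,
                noise_sigma_gv=sc.noise_sigma_gv,
                fade_tau_s=sc.fade_tau_s,
            )
        except ValueError as exc:
            raise ConfigError(f"system {name!r}: {exc}") from exc
    return out


def geometry_from_config(config: RunConfig) -> PhantomGeometry:
    g = config.geometry
    return build_geometry(
        rows=g.rows, cols=g.cols,
        wedge_row_start=g.wedge_row_start,
        step_height_px=g.step_height_px,
        wedge_col_start=g.wedge_col_start,
        wedge_col_stop=g.wedge_col_stop,
        n_steps=g.n_steps,
        thickness_increment_mm=g.thickness_increment_mm,
    )
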