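"""Configuration loading and validation.

A configuration is a nested dict with four blocks: ``network`` (segments,
connectivity, Windkessel totals, measurement sites), ``ranges`` (healthy
sampling intervals for the cohort), ``numerics`` (solver controls) and
``cohort`` (size and seed). :func:`load_config` merges a user YAML/JSON
file over the built-in defaults; the numeric blocks are validated with
pydantic models, the network block structurally by
:func:`pulsebench.virtual_cohort.build_reduced_network`.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from ._defaults import default_config
from .errors import ConfigError


class NumericsConfig(BaseModel):
    """Solver controls; defaults give a CFL-stable desk-scale run."""

    dx: float = Field(2.5e-3, gt=0)
    cfl: float = Field(0.9, gt=0, le=1.0)
    blood_viscosity: float = Field(4.0e-3, gt=0)
    profile_zeta: float = Field(9.0, ge=0)
    p_ref_mmhg: float = 75.0
    max_cycles: int = Field(30, ge=1)
    min_cycles: int = Field(5, ge=1)
    periodicity_tol_mmhg: float = Field(0.1, gt=0)
    output_rate: float = Field(1000.0, gt=0)
    backflow_fraction: float = Field(0.02, ge=0, lt=0.5)
    backflow_duration: float = Field(0.06, ge=0)
    ejection_rise_fraction: float = Field(0.3, ge=0.05, le=0.95)

    @model_validator(mode="after")
    def _check(self):
        if self.min_cycles > self.max_cycles:
            raise ValueError("min_cycles must not exceed max_cycles")
        return self


class CohortConfig(BaseModel):
    n: int = Field(50, ge=1)
    seed: int = Field(20161208, ge=0)


RANGE_KEYS = (
    "heart_rate",
    "stroke_volume",
    "ejection_time",
    "c_el_factor",
    "muscular_stiffness_scale",
    "diameter_scale",
    "peripheral_resistance_scale",
    "peripheral_compliance_scale",
)


def validate_ranges(ranges: dict) -> dict[str, tuple[float, float]]:
    """Check that every sampling range is present and not inverted."""
    out = {}
    for key in RANGE_KEYS:
        if key not in ranges:
            raise ConfigError(f"missing sampling range: {key!r}")
        lo, hi = ranges[key]
        lo, hi = float(lo), float(hi)
        if hi < lo:
            raise ConfigError(f"inverted range for {key!r}: [{lo}, {hi}]")
        out[key] = (lo, hi)
    return out


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Return the full configuration, merging a YAML/JSON file over defaults."""
    cfg = default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if user:
            cfg = _merge(cfg, user)
    # validate the numeric blocks early so errors carry context
    try:
        cfg["numerics"] = NumericsConfig(**cfg.get("numerics", {})).model_dump()
        cfg["cohort"] = CohortConfig(**cfg.get("cohort", {})).model_dump()
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    validate_ranges(cfg.get("ranges", {}))
    return cfg
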