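"""YAML run configuration: strict parsing, defaults and config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .fluids import FluidProperties, water_properties
from .geometry import WellGeometry
from .motion import MotionSettings
from .solver import SolverConfig
from .thermal import PIDGains, ThermalPlant

__all__ = ["RunConfig", "load_config", "config_hash"]

_GEOMETRY_KEYS = {
    "length_m": "length",
    "width_m": "width",
    "capacity_m3": "capacity",
    "pivot_x_m": "pivot_x",
    "max_depth_m": "max_depth",
}
_MOTION_KEYS = {
    "max_angle_deg": "max_angle_deg",
    "max_speed_deg_s": "max_speed_deg_s",
    "max_accel_deg_s2": "max_accel_deg_s2",
}
_FLUID_KEYS = {"temperature_C", "rho", "mu"}
_SOLVER_KEYS = {
    "n_cells": "n_cells",
    "cfl_number": "cfl_number",
    "dry_threshold_m": "dry_threshold",
    "spinup_periods": "spinup_periods",
    "record_periods": "record_periods",
    "include_euler_forcing": "include_euler_forcing",
    "output_hz": "output_hz",
    "state_hz": "state_hz",
}
_ANALYSIS_KEYS = {
    "speeds_deg_s",
    "exceedance_threshold_Pa",
    "cell_area_m2",
    "mask_basis",
}
_PLANT_KEYS = {
    "c_plate",
    "c_water",
    "k_plate_water",
    "k_plate_ambient",
    "k_water_ambient",
    "ambient_c",
    "heat_power_w",
    "cool_power_w",
}
_GAINS_KEYS = {"kp", "ki", "kd", "output_limit", "sample_interval", "integral_limit"}
_THERMAL_KEYS = {"plant", "gains", "setpoint_C", "duration_s"}
_OUTPUT_KEYS = {"directory"}
_TOP_KEYS = {
    "geometry",
    "motion",
    "fluid",
    "fill_volume_ml",
    "solver",
    "analysis",
    "thermal",
    "output",
}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown config keys in {where}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def _mapped(section: dict, mapping: dict, where: str) -> dict:
    _check_keys(section, mapping, where)
    return {mapping[k]: v for k, v in section.items()}


@dataclass
class RunConfig:
    """Validated run configuration with provenance hash."""

    geometry: WellGeometry
    motion: MotionSettings
    fluid: FluidProperties
    solver: SolverConfig
    fill_volume_m3: float
    analysis: dict = field(default_factory=dict)
    thermal_plant: ThermalPlant = field(default_factory=ThermalPlant)
    thermal_gains: PIDGains = field(default_factory=PIDGains)
    thermal_setpoint_c: float = 37.0
    thermal_duration_s: float = 900.0
    output_dir: str = "out"
    hash: str = ""
    raw: dict = field(default_factory=dict)


def config_hash(raw: dict) -> str:
    """Stable short hash of the raw configuration mapping."""
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path=None, raw: dict | None = None) -> RunConfig:
    """Load and validate a YAML config (or an already-parsed mapping).

    Unknown keys anywhere in the file are rejected with a message
    listing the offending keys.
    """
    if raw is None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    _check_keys(raw, _TOP_KEYS, "top level")

    geometry = WellGeometry(**_mapped(raw.get("geometry", {}) or {}, _GEOMETRY_KEYS, "geometry"))

    motion_raw = raw.get("motion", {}) or {}
    motion = MotionSettings(
        **_mapped(
            {"max_angle_deg": 7.0, "max_speed_deg_s": 40.0, **motion_raw},
            _MOTION_KEYS,
            "motion",
        )
    )

    fluid_raw = raw.get("fluid", {}) or {}
    _check_keys(fluid_raw, _FLUID_KEYS, "fluid")
    if "rho" in fluid_raw or "mu" in fluid_raw:
        if not {"rho", "mu"} <= set(fluid_raw):
            raise ConfigError("fluid: rho and mu must be given together")
        fluid = FluidProperties(
            density=float(fluid_raw["rho"]),
            viscosity=float(fluid_raw["mu"]),
            temperature=fluid_raw.get("temperature_C"),
        )
    else:
        fluid = water_properties(float(fluid_raw.get("temperature_C", 37.0)))

    solver_raw = _mapped(raw.get("solver", {}) or {}, _SOLVER_KEYS, "solver")
    solver = SolverConfig(**solver_raw)

    fill_ml = float(raw.get("fill_volume_ml", 5.0))
    if fill_ml <= 0:
        raise ConfigError(f"fill_volume_ml must be positive, got {fill_ml}")

    analysis = dict(raw.get("analysis", {}) or {})
    _check_keys(analysis, _ANALYSIS_KEYS, "analysis")

    thermal_raw = raw.get("thermal", {}) or {}
    _check_keys(thermal_raw, _THERMAL_KEYS, "thermal")
    plant_raw = thermal_raw.get("plant", {}) or {}
    _check_keys(plant_raw, _PLANT_KEYS, "thermal.plant")
    gains_raw = thermal_raw.get("gains", {}) or {}
    _check_keys(gains_raw, _GAINS_KEYS, "thermal.gains")

    output_raw = raw.get("output", {}) or {}
    _check_keys(output_raw, _OUTPUT_KEYS, "output")

    return RunConfig(
        geometry=geometry,
        motion=motion,
        fluid=fluid,
        solver=solver,
        fill_volume_m3=fill_ml * 1e-6,
        analysis=analysis,
        thermal_plant=ThermalPlant(**plant_raw),
        thermal_gains=PIDGains(**gains_raw),
        thermal_setpoint_c=float(thermal_raw.get("setpoint_C", 37.0)),
        thermal_duration_s=float(thermal_raw.get("duration_s", 900.0)),
        output_dir=str(output_raw.get("directory", "out")),
        hash=config_hash(raw),
        raw=raw,
    )
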