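"""Run configuration: structured-file parsing, validation, unit handling.

Configs are YAML (JSON, being a YAML subset, is accepted too) with the
layout

    implant:
      preset: implant_A            # or explicit length/diffusivity
      # length: 13 mm
      # diffusivity: 2e-6
    load:
      t_hot: 60
      t_body: 37
      exposure_time: 2
    series:
      n_terms: 200
      resonance_tol: 1e-8
    grid:
      times: [0, 1, 2]             # or {start, stop, num}
      positions: [0, 0.0065, 0.013]   # or named_points: [B1, B2]

Lengths accept explicit unit suffixes (mm, cm, m) and are normalised
to SI metres; temperatures are degC throughout, times seconds.
Validation errors name the offending key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .scenarios import LocationPoint, location_y, preset_model
from .thermal_model import EvaluationGrid, ImplantModel, SeriesConfig, ThermalLoad

__all__ = ["ConfigError", "RunConfig", "parse_config", "parse_length"]

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}


class ConfigError(ValueError):
    """A configuration problem, carrying the offending key in its message."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated, SI-normalised run description."""

    model: ImplantModel
    load: ThermalLoad
    series: SeriesConfig
    grid: EvaluationGrid | None = None
    named_points: tuple[str, ...] = ()


def parse_length(value, key: str = "length") -> float:
    """A length given as a bare number (metres) or '<number> <unit>' string."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2 and parts[1] in _LENGTH_UNITS:
            try:
                return float(parts[0]) * _LENGTH_UNITS[parts[1]]
            except ValueError:
                pass
        raise ConfigError(
            f"{key}: cannot parse length {value!r}; use a number in metres "
            f"or '<number> <mm|cm|m>'"
        )
    raise ConfigError(f"{key}: expected a number or a '<number> <unit>' string")


def _require_mapping(obj, key: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{key}: expected a mapping")
    return obj


def _check_keys(section: dict, allowed: set[str], key: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{key}: unknown key(s) {sorted(unknown)}")


def _parse_implant(section: dict) -> ImplantModel:
    _check_keys(section, {"preset", "length", "diffusivity", "label"}, "implant")
    has_preset = "preset" in section
    has_explicit = "length" in section or "diffusivity" in section
    if has_preset and has_explicit:
        raise ConfigError(
            "implant: give either 'preset' or explicit 'length'/'diffusivity', not both"
        )
    if has_preset:
        try:
            return preset_model(section["preset"])
        except KeyError as exc:
            raise ConfigError(f"implant.preset: {exc.args[0]}") from None
    if "length" not in section or "diffusivity" not in section:
        raise ConfigError(
            "implant: explicit implants need both 'length' and 'diffusivity'"
        )
    length = parse_length(section["length"], key="implant.length")
    try:
        diffusivity = float(section["diffusivity"])
    except (TypeError, ValueError):
        raise ConfigError("implant.diffusivity: expected a number in m^2/s") from None
    try:
        return ImplantModel(length, diffusivity, label=str(section.get("label", "")))
    except ValueError as exc:
        raise ConfigError(f"implant: {exc}") from None


def _parse_load(section: dict) -> ThermalLoad:
    _check_keys(section, {"t_hot", "t_body", "exposure_time"}, "load")
    kwargs = {}
    for name in ("t_hot", "t_body", "exposure_time"):
        if name in section:
            try:
                kwargs[name] = float(section[name])
            except (TypeError, ValueError):
                raise ConfigError(f"load.{name}: expected a number") from None
    try:
        return ThermalLoad(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"load: {exc}") from None


def _parse_series(section: dict) -> SeriesConfig:
    _check_keys(section, {"n_terms", "resonance_tol"}, "series")
    kwargs = {}
    if "n_terms" in section:
        kwargs["n_terms"] = int(section["n_terms"])
    if "resonance_tol" in section:
        kwargs["resonance_tol"] = float(section["resonance_tol"])
    try:
        return SeriesConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"series: {exc}") from None


def _parse_axis(value, key: str) -> list[float]:
    if isinstance(value, dict):
        _check_keys(value, {"start", "stop", "num"}, key)
        try:
            return list(
                np.linspace(float(value["start"]), float(value["stop"]),
                            int(value["num"]))
            )
        except (KeyError, TypeError, ValueError):
            raise ConfigError(
                f"{key}: range form needs numeric 'start', 'stop' and integer 'num'"
            ) from None
    if isinstance(value, (list, tuple)):
        try:
            return [float(v) for v in value]
        except (TypeError, ValueError):
            raise ConfigError(f"{key}: expected a list of numbers") from None
    raise ConfigError(f"{key}: expected a list or a {{start, stop, num}} mapping")


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed config: {exc}") from None
    raw = _require_mapping(raw, str(path))
    _check_keys(raw, {"implant", "load", "series", "grid"}, "top level")

    model = _parse_implant(_require_mapping(raw.get("implant"), "implant"))
    load = _parse_load(_require_mapping(raw.get("load"), "load"))
    series = _parse_series(_require_mapping(raw.get("series"), "series"))

    grid = None
    named: tuple[str, ...] = ()
    if "grid" in raw:
        section = _require_mapping(raw["grid"], "grid")
        _check_keys(section, {"times", "positions", "named_points"}, "grid")
        if "positions" in section and "named_points" in section:
            raise ConfigError("grid: give either 'positions' or 'named_points'")
        times = _parse_axis(section.get("times", []), "grid.times") or None
        if "named_points" in section:
            points = section["named_points"]
            if not isinstance(points, (list, tuple)) or not points:
                raise ConfigError("grid.named_points: expected a non-empty list")
            try:
                named = tuple(str(p) for p in points)
                positions = [
                    location_y(LocationPoint.named(p), model) for p in named
                ]
            except KeyError as exc:
                raise ConfigError(f"grid.named_points: {exc.args[0]}") from None
            positions.sort()
        elif "positions" in section:
            positions = [
                parse_length(v, key="grid.positions") for v in section["positions"]
            ]
        else:
            positions = None
        if times is not None and positions is not None:
            try:
                grid = EvaluationGrid(times, positions)
                grid.validate_for(model)
            except ValueError as exc:
                raise ConfigError(f"grid: {exc}") from None
    return RunConfig(model=model, load=load, series=series, grid=grid,
                     named_points=named)
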