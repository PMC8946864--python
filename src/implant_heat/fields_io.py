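"""Tabular writers/readers for temperature fields and golden fixtures.

CSV layout is long-format, time-outer: ``t_s, y_m, temperature_C,
method`` with one row per (time, position) cell.  Values are written at
17 significant digits so a write/read round trip reproduces the field
bit-for-bit.  JSON output carries a full provenance block (implant,
load, series or FD configuration) sufficient to re-run the computation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import scenarios
from .thermal_model import ImplantModel, TemperatureField, ThermalLoad

__all__ = [
    "field_to_frame",
    "write_field",
    "read_field",
    "field_provenance",
    "generate_golden_fixtures",
]

_FMT = "%.17g"


def field_to_frame(field: TemperatureField) -> pd.DataFrame:
    """Long-format (time-outer) DataFrame of a temperature field."""
    tt, yy = np.meshgrid(field.times, field.positions, indexing="ij")
    return pd.DataFrame({
        "t_s": tt.ravel(),
        "y_m": yy.ravel(),
        "temperature_C": field.values.ravel(),
        "method": field.method,
    })


def field_provenance(field: TemperatureField) -> dict:
    """JSON-serialisable provenance: model, load and configuration."""
    cfg = field.config
    return {
        "method": field.method,
        "implant": {
            "length_m": field.model.length,
            "diffusivity_m2_s": field.model.diffusivity,
            "label": field.model.label,
            "intrinsic_time_s": field.model.intrinsic_time,
        },
        "load": {
            "t_hot_C": field.load.t_hot,
            "t_body_C": field.load.t_body,
            "exposure_time_s": field.load.exposure_time,
            "delta_t_C": field.load.delta_t,
        },
        "config": asdict(cfg) if is_dataclass(cfg) else None,
        "n_times": int(field.times.size),
        "n_positions": int(field.positions.size),
    }


def write_field(field: TemperatureField, path: str | Path, format: str = "csv") -> Path:
    """Write a field as CSV (with a JSON provenance sidecar) or JSON.

    CSV rows are time-outer; the sidecar lands next to the CSV with a
    ``.provenance.json`` suffix.  JSON output embeds values and
    provenance in one document.
    """
    path = Path(path)
    try:
        if format == "csv":
            field_to_frame(field).to_csv(path, index=False, float_format=_FMT)
            sidecar = path.with_suffix(".provenance.json")
            sidecar.write_text(json.dumps(field_provenance(field), indent=2) + "\n")
        elif format == "json":
            doc = field_provenance(field)
            doc["times_s"] = field.times.tolist()
            doc["positions_m"] = field.positions.tolist()
            doc["values_C"] = field.values.tolist()
            path.write_text(json.dumps(doc, indent=2) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")
    except OSError as exc:
        raise OSError(f"cannot write field to {path}: {exc}") from exc
    return path


def read_field(
    csv_path: str | Path, model: ImplantModel, load: ThermalLoad
) -> TemperatureField:
    """Reconstruct a field from its CSV (provenance supplied by caller)."""
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    times = np.unique(frame["t_s"].to_numpy())
    positions = np.unique(frame["y_m"].to_numpy())
    values = frame["temperature_C"].to_numpy().reshape(times.size, positions.size)
    return TemperatureField(
        times=times, positions=positions, values=values,
        method=str(frame["method"].iloc[0]), model=model, load=load,
    )


def generate_golden_fixtures(output_dir: str | Path) -> list[Path]:
    """Deterministic regression fixtures: figure datasets + preset times.

    Writes ``figure_N.csv`` for every standard figure dataset and
    ``preset_intrinsic_times.json``; byte-identical across runs (the
    artifact contains no randomness anywhere).
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fig_id in (2, 3, 4, 5, 6, 7):
        path = output_dir / f"figure_{fig_id}.csv"
        scenarios.figure_dataset(fig_id).to_csv(path, index=False, float_format=_FMT)
        written.append(path)
    taus = {
        name: model.intrinsic_time for name, model in scenarios.PRESETS.items()
    }
    path = output_dir / "preset_intrinsic_times.json"
    path.write_text(json.dumps(taus, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
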