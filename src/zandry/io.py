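"""Config files and CSV dialects.

One human-readable YAML config with flat keys per section (``material``,
``schedule``, ``simulation``) describes a drying scenario; the bundled
default reproduces the study's operating-parameter table verbatim.  CSV
files are comma-separated, UTF-8, with a mandatory header row and '.'
decimals: drying curves (time_h or time_min, moisture_db, optional temp_c),
quality tables (treatment + indicator columns) and color replicates
(treatment, replicate, L, a, b).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kinetics import DryingCurve
from .properties import MaterialProperties, PulsationSchedule
from .quality import INDICATOR_COLUMNS, QualityTable
from .simulator import SimulationConfig, SimulationResult

__all__ = [
    "default_config",
    "load_config",
    "dump_config",
    "read_drying_curve",
    "write_drying_curve",
    "read_quality_table",
    "write_quality_table",
    "read_color_replicates",
    "write_simulation_result",
]


def default_config() -> dict:
    """The bundled default configuration (study operating parameters)."""
    return {
        "material": dataclasses.asdict(MaterialProperties()),
        "schedule": dataclasses.asdict(PulsationSchedule()),
        "simulation": _simulation_dict(SimulationConfig()),
    }


def _simulation_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["mode"] = cfg.mode.value
    d.pop("schedule", None)  # stored in its own section
    return d


def load_config(
    path: "str | Path | None" = None, overrides: "dict | None" = None
) -> tuple[MaterialProperties, PulsationSchedule, SimulationConfig]:
    """Load (properties, schedule, simulation config) from a YAML file.

    Missing keys fall back to the bundled defaults; ``overrides`` is a
    mapping of section name to key/value overrides applied last.
    """
    data = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root must be a mapping: {path}")
        for section, values in user.items():
            if section not in data:
                raise ValueError(f"unknown config section {section!r}")
            if values:
                unknown = set(values) - set(data[section])
                if unknown:
                    raise ValueError(
                        f"unknown keys in [{section}]: {sorted(unknown)}"
                    )
                data[section].update(values)
    for section, values in (overrides or {}).items():
        data[section].update(values)
    props = MaterialProperties(**data["material"])
    schedule = PulsationSchedule(**data["schedule"])
    sim = SimulationConfig(schedule=schedule, **data["simulation"])
    return props, schedule, sim


def dump_config(path: "str | Path", config: "dict | None" = None) -> None:
    """Write a config mapping (default: the bundled defaults) as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config or default_config(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# drying curves


def read_drying_curve(path: "str | Path") -> DryingCurve:
    """Read a drying-curve CSV (columns time_h|time_min, moisture_db[, temp_c])."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_h" in cols:
        times_h = df[cols["time_h"]].to_numpy(float)
    elif "time_min" in cols:
        times_h = df[cols["time_min"]].to_numpy(float) / 60.0
    else:
        raise ValueError(f"{path}: need a time_h or time_min column")
    if "moisture_db" not in cols:
        raise ValueError(f"{path}: need a moisture_db column")
    temp = df[cols["temp_c"]].to_numpy(float) if "temp_c" in cols else None
    return DryingCurve(
        times_h=times_h,
        moisture=df[cols["moisture_db"]].to_numpy(float),
        surface_temperature=temp,
        method=str(df[cols["method"]].iloc[0]) if "method" in cols else "",
        temperature=float(df[cols["temperature_c"]].iloc[0])
        if "temperature_c" in cols
        else None,
    )


def write_drying_curve(curve: DryingCurve, path: "str | Path") -> None:
    df = pd.DataFrame({"time_h": curve.times_h, "moisture_db": curve.moisture})
    if curve.surface_temperature is not None:
        df["temp_c"] = curve.surface_temperature
    if curve.method:
        df["method"] = curve.method
    if curve.temperature is not None:
        df["temperature_c"] = curve.temperature
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality tables and color replicates


def read_quality_table(path: "str | Path") -> QualityTable:
    """Read a quality-table CSV: treatment column + indicator columns.

    Optional ``<indicator>_sd`` columns populate the SD table.
    """
    df = pd.read_csv(path)
    if "treatment" not in df.columns:
        raise ValueError(f"{path}: need a 'treatment' column")
    df = df.set_index("treatment")
    missing = [c for c in INDICATOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing indicator columns {missing}")
    means = df[list(INDICATOR_COLUMNS)].astype(float)
    sd_cols = {c: f"{c}_sd" for c in INDICATOR_COLUMNS if f"{c}_sd" in df.columns}
    sds = None
    if sd_cols:
        sds = df[list(sd_cols.values())].astype(float)
        sds.columns = list(sd_cols)
    return QualityTable(means=means, sds=sds)


def write_quality_table(table: QualityTable, path: "str | Path") -> None:
    out = table.means.copy()
    if table.sds is not None:
        for c in table.sds.columns:
            out[f"{c}_sd"] = table.sds[c]
    out.index.name = "treatment"
    out.to_csv(path)


def read_color_replicates(path: "str | Path") -> pd.DataFrame:
    """Read replicate-level CIELAB readings (treatment, replicate, L, a, b)."""
    df = pd.read_csv(path)
    required = {"treatment", "replicate", "L", "a", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# simulation exports


def write_simulation_result(
    result: SimulationResult, out_dir: "str | Path", stem: str = "run"
) -> dict:
    """Export a simulation: field CSV, summary CSV and ledger/metadata JSON.

    Returns the mapping of artifact name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fields": out / f"{stem}_fields.csv",
        "summary": out / f"{stem}_summary.csv",
        "ledger": out / f"{stem}_ledger.json",
    }
    result.to_field_frame().to_csv(paths["fields"], index=False)
    result.to_summary_frame().to_csv(paths["summary"], index=False)
    meta = {
        "mode": result.config.mode.value,
        "geometry": result.config.geometry,
        "air_temperature_c": result.config.air_temperature,
        "n_nodes": result.config.n_nodes,
        "drying_time_to_target_s": result.drying_time_to_target,
        "energy_ledger": result.energy_ledger,
        "mass_ledger": result.mass_ledger,
    }
    with open(paths["ledger"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
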