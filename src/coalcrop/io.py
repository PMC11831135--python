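"""Table schemas, validated CSV I/O and run configuration.

All interchange is UTF-8 CSV with ISO-8601 dates and "." decimals.
Coordinates are WGS84 decimal degrees, latitude before longitude. Units
are fixed per column: GWh, umol/m2, degC, mm, metric tons, USD.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exposure import OCTANTS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    pass


def _v_lat(s):
    return (s >= -90) & (s <= 90)


def _v_lon(s):
    return (s >= -180) & (s <= 180)


def _v_nonneg(s):
    return s >= 0


def _v_octant(s):
    return s.isin(OCTANTS)


def _v_crop(s):
    return s.isin(["rice", "wheat"])


def _v_cropfrac(s):
    return (s > 0) & (s <= 1)


def _v_finite(s):
    return np.isfinite(s)


def _v_date(s):
    return pd.to_datetime(s, format="%Y-%m-%d", errors="coerce").notna()


# schema: column -> (dtype kind, row validator or None)
SCHEMAS = {
    "stations": {
        "station_id": ("str", None),
        "lat": ("float", _v_lat),
        "lon": ("float", _v_lon),
        "state": ("str", None),
    },
    "generation": {
        "station_id": ("str", None),
        "date": ("str", _v_date),
        "generation_gwh": ("float", _v_nonneg),
    },
    "wind": {
        "station_id": ("str", None),
        "date": ("str", _v_date),
        "wind_from_octant": ("str", _v_octant),
    },
    "points": {
        "point_id": ("str", None),
        "lat": ("float", _v_lat),
        "lon": ("float", _v_lon),
        "state": ("str", None),
        "crop_fraction": ("float", _v_cropfrac),
    },
    "point_seasons": {
        "point_id": ("str", None),
        "season_id": ("str", None),
        "no2_umol_m2": ("float", _v_finite),
        "nirv": ("float", _v_finite),
        "temp_c": ("float", _v_finite),
        "precip_mm": ("float", _v_finite),
    },
    "seasons": {
        "season_id": ("str", None),
        "crop": ("str", _v_crop),
        "year": ("int", None),
        "start_date": ("str", _v_date),
        "end_date": ("str", _v_date),
    },
    "output": {
        "state": ("str", None),
        "season_id": ("str", None),
        "output_tons": ("float", _v_nonneg),
    },
    "mortality": {
        "station_id": ("str", None),
        "deaths_per_gwh": ("float", _v_nonneg),
        "mortality_usd_lo": ("float", _v_finite),
        "mortality_usd_hi": ("float", _v_finite),
    },
}

_DTYPES = {"str": str, "float": float, "int": int}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate one input CSV against its schema.

    Raises SchemaError with offending row numbers (1-based, excluding the
    header) on missing columns, unparseable values or range violations.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col, (kind, validator) in schema.items():
        try:
            df[col] = df[col].astype(_DTYPES[kind])
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path}: column {col!r} not parseable as {kind}: {e}")
        if validator is not None:
            ok = validator(df[col])
            if not ok.all():
                rows = (np.flatnonzero(~ok) + 1).tolist()[:20]
                raise SchemaError(
                    f"{path}: column {col!r} failed validation at rows {rows}"
                )
    logger.info("read %s: %d rows from %s", schema_name, len(df), path)
    return df[list(schema)]


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV losslessly (17 significant digits round-trips float64)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


TABLE_NAMES = tuple(SCHEMAS)


def read_tables(data_dir) -> dict:
    """Read all eight input tables from a directory of <name>.csv files."""
    data_dir = Path(data_dir)
    tables = {}
    for name in TABLE_NAMES:
        p = data_dir / f"{name}.csv"
        if p.exists():
            tables[name] = read_table(p, name)
        elif name in ("output", "mortality"):
            tables[name] = None  # optional downstream tables
        else:
            raise FileNotFoundError(f"required input table missing: {p}")
    return tables


def write_tables(tables: dict, data_dir) -> None:
    data_dir = Path(data_dir)
    for name, df in tables.items():
        if df is not None:
            write_table(df, data_dir / f"{name}.csv")


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run (YAML-backed)."""

    data_dir: str = "inputs"
    output_dir: str = "outputs"
    seed: int = 0
    target_year: int | None = None
    exclude_stations: list = field(default_factory=list)
    econ: dict = field(default_factory=dict)  # EconomicParams overrides
    bootstrap: dict = field(default_factory=dict)  # n_iterations, level, ...
    run_bootstrap: bool = False
    policy_budget_fraction: float = 0.10
    objectives: list = field(default_factory=lambda: ["mortality", "crop", "combined"])
    simulate: dict | None = None  # WorldConfig overrides; triggers simulation
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the semantically meaningful fields (log level excluded)."""
        payload = {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
            if k not in ("log_level",)
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
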