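"""End-to-end pipeline: simulate -> exposure -> fit -> attribute -> damages
-> bootstrap (optional) -> optimize (optional).

Every run writes artifacts stamped with the configuration hash and seed so
re-running an identical configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .damages import EconomicParams
from .io import RunConfig, read_tables, write_table, write_tables
from .model import CoalAttributionModel
from .synth import WorldConfig, generate_world
from .uncertainty import BootstrapConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "exposure", "fit", "attribute", "damages", "bootstrap", "optimize")


def simulate_stage(config: RunConfig) -> dict:
    """Generate a synthetic world and write its input tables."""
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", config.seed)
    for key in ("years", "bbox", "nirv_range", "weather_betas", "capacity_range_gwh"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    world = generate_world(WorldConfig(**overrides))
    tables = world.tables()
    write_tables(tables, config.data_dir)
    truth_path = Path(config.data_dir) / "truth.json"
    truth_path.parent.mkdir(parents=True, exist_ok=True)
    truth = {
        "true_betas": {f"{cat}|{band}": v for (cat, band), v in world.truth["true_betas"].items()},
        "weather_betas": list(world.truth["weather_betas"]),
        "no2_baseline": world.truth["no2_baseline"],
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    logger.info("simulated world with %d points, %d stations", len(world.points), len(world.stations))
    return tables


def build_model(config: RunConfig, tables: dict | None = None) -> CoalAttributionModel:
    if tables is None:
        tables = read_tables(config.data_dir)
    econ = EconomicParams(**config.econ)
    return CoalAttributionModel.from_tables(
        tables, econ=econ, exclude_stations=config.exclude_stations
    )


def run_pipeline(config: RunConfig, upto: str = "optimize") -> Path:
    """Run the pipeline through stage ``upto``; returns the artifact dir."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; stages are {STAGES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = {s: i for i, s in enumerate(STAGES)}
    stop = order[upto]

    tables = None
    if config.simulate is not None:
        tables = simulate_stage(config)
    if stop < order["exposure"]:
        _manifest(config, out)
        return out

    try:
        model = build_model(config, tables)
        write_table(model.exposures, out / "exposure.csv")
        if stop >= order["fit"]:
            results = model.fit()
            fits_json = {
                f"{st}|{band}": fit.to_dict() for (st, band), fit in results.band_fits.items()
            }
            (out / "fits.json").write_text(json.dumps(fits_json, indent=1, sort_keys=True))
        if stop >= order["attribute"]:
            totals, by_station = results.attribute()
            write_table(totals, out / "attribution.csv")
            write_table(by_station, out / "attribution_by_station.csv")
            write_table(results.attribution_summary(), out / "attribution_state.csv")
        if stop >= order["damages"] and model.output is not None:
            tabs = results.damages(year=config.target_year)
            write_table(tabs["state"], out / "damages_state.csv")
            write_table(tabs["station"], out / "damages_station.csv")
            write_table(tabs["intensity"], out / "intensities.csv")
        boots = None
        if stop >= order["bootstrap"] and config.run_bootstrap and model.output is not None:
            boots = {}
            for i, st in enumerate(("monsoon", "winter")):
                bc = BootstrapConfig(
                    season_type=st, seed=config.seed + 1000 + i, **config.bootstrap
                )
                boots[st] = results.bootstrap(bc, target_year=config.target_year)
            frames = [
                res.to_frame().assign(season_type=st)
                for st, group in boots.items()
                for res in group.values()
            ]
            write_table(pd.concat(frames, ignore_index=True), out / "bootstrap.csv")
        if stop >= order["optimize"] and model.mortality is not None and model.output is not None:
            ledger, seasonal = results.station_ledger(
                year=config.target_year, bootstrap_results=boots
            )
            write_table(ledger.sort_values("crop_intensity_annual", ascending=False),
                        out / "station_ledger.csv")
            scenarios = {}
            for obj in config.objectives:
                scen = results.scenario(
                    obj,
                    budget_fraction=config.policy_budget_fraction,
                    year=config.target_year,
                    bootstrap_results=boots,
                )
                scenarios[obj] = scen.to_dict()
                (out / f"scenario_{obj}.json").write_text(
                    json.dumps(scen.to_dict(), indent=1, sort_keys=True, default=str)
                )
    except Exception as e:
        (out / "failure.json").write_text(
            json.dumps({"stage_error": str(e), "config_hash": config.config_hash()})
        )
        raise
    _manifest(config, out)
    return out


def _manifest(config: RunConfig, out: Path) -> None:
    (out / "run_manifest.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "config": dataclasses.asdict(config),
            },
            indent=1,
            sort_keys=True,
            default=str,
        )
    )
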