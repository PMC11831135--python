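"""Model/Results front end tying the pipeline stages together.

``CoalAttributionModel`` is constructed from the eight input tables (or a
``SyntheticWorld``), precomputes the directional exposure regressors, and
``fit()`` estimates the per-band fixed-effects models. The returned
``CoalAttributionResults`` carries the coefficient estimates with their
clustered covariances and exposes the downstream stages — attribution,
damages, bootstrap intervals, the station ledger and policy scenarios — as
methods, in the spirit of a statsmodels results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import damages as dmg
from .attribution import attribute_no2, fit_all_bands
from .damages import EconomicParams
from .exposure import build_exposure, pair_geometry, station_direction_totals
from .policy import PolicyScenario, rank_and_select, seasonal_selection
from .uncertainty import BootstrapConfig, bootstrap_run


class CoalAttributionModel:
    """Wind-direction exposure model for coal-attributable NO2 over cropland.

    Parameters are the validated input tables; see the io module for the
    column schemas. ``exclude_stations`` removes stations from exposure
    construction and all downstream accounting.
    """

    def __init__(
        self,
        stations: pd.DataFrame,
        points: pd.DataFrame,
        wind: pd.DataFrame,
        generation: pd.DataFrame,
        seasons: pd.DataFrame,
        point_seasons: pd.DataFrame,
        output: pd.DataFrame | None = None,
        mortality: pd.DataFrame | None = None,
        econ: EconomicParams | None = None,
        exclude_stations=(),
    ):
        excl = set(exclude_stations)
        if excl:
            stations = stations[~stations["station_id"].isin(excl)].reset_index(drop=True)
            wind = wind[~wind["station_id"].isin(excl)]
            generation = generation[~generation["station_id"].isin(excl)]
            if mortality is not None:
                mortality = mortality[~mortality["station_id"].isin(excl)]
        self.stations = stations
        self.points = points
        self.wind = wind
        self.generation = generation
        self.seasons = seasons
        self.point_seasons = point_seasons
        self.output = output
        self.mortality = mortality
        self.econ = econ if econ is not None else EconomicParams()

        self.observations = point_seasons.merge(
            points[["point_id", "state", "crop_fraction"]], on="point_id"
        )
        self.direction_totals = station_direction_totals(generation, wind, seasons)
        self.pairs = pair_geometry(points, stations)
        self.exposures = build_exposure(
            points, stations, self.direction_totals, pairs=self.pairs
        )
        self.per_station_exposures = build_exposure(
            points, stations, self.direction_totals, pairs=self.pairs, per_station=True
        )

    @classmethod
    def from_world(cls, world, **kwargs) -> "CoalAttributionModel":
        """Build from a SyntheticWorld."""
        return cls(
            stations=world.stations,
            points=world.points,
            wind=world.wind,
            generation=world.generation,
            seasons=world.seasons,
            point_seasons=world.point_seasons,
            output=world.output,
            mortality=world.mortality,
            **kwargs,
        )

    @classmethod
    def from_tables(cls, tables: dict, **kwargs) -> "CoalAttributionModel":
        return cls(
            stations=tables["stations"],
            points=tables["points"],
            wind=tables["wind"],
            generation=tables["generation"],
            seasons=tables["seasons"],
            point_seasons=tables["point_seasons"],
            output=tables.get("output"),
            mortality=tables.get("mortality"),
            **kwargs,
        )

    def fit(self, weather=("temp_c", "precip_mm"), quadratic_weather=False):
        """Estimate the ten distance-band models per season type."""
        fits = fit_all_bands(
            self.observations,
            self.exposures,
            self.seasons,
            weather=weather,
            quadratic_weather=quadratic_weather,
        )
        return CoalAttributionResults(self, fits)


@dataclass
class CoalAttributionResults:
    model: CoalAttributionModel
    band_fits: dict  # (season_type, band) -> DistanceBandFit

    def summary(self) -> pd.DataFrame:
        """Stacked coefficient table across season types and bands."""
        rows = []
        for (st, band), fit in sorted(self.band_fits.items()):
            tab = fit.summary().reset_index(names="term")
            tab.insert(0, "season_type", st)
            tab.insert(1, "band", band)
            tab["n_obs"] = fit.n_obs
            tab["n_clusters"] = fit.n_clusters
            rows.append(tab)
        return pd.concat(rows, ignore_index=True)

    def attribute(self):
        """Point-level attributable NO2: (totals, per-station decomposition)."""
        return attribute_no2(
            self.model.exposures,
            self.band_fits,
            self.model.seasons,
            per_station_exposures=self.model.per_station_exposures,
        )

    def attribution_summary(self) -> pd.DataFrame:
        """State x season mean observed and attributable NO2 (+ percent)."""
        totals, _ = self.attribute()
        merged = self.model.observations.merge(
            totals, on=["point_id", "season_id"], how="left"
        )
        merged["coal_no2_total"] = merged["coal_no2_total"].fillna(0.0)
        agg = merged.groupby(["state", "season_id"], as_index=False).agg(
            mean_no2=("no2_umol_m2", "mean"),
            mean_coal_no2=("coal_no2_total", "mean"),
        )
        agg["pct_attributable"] = 100.0 * agg["mean_coal_no2"] / agg["mean_no2"]
        return agg

    def damages(self, year: int | None = None) -> dict:
        """State and station damage tables plus intensities for one year."""
        if self.model.output is None:
            raise ValueError("damages require the state output table")
        seasons = self.model.seasons
        if year is None:
            year = int(seasons["year"].max())
        econ = self.model.econ
        totals, by_station = self.attribute()
        year_ids = seasons.loc[seasons["year"] == year, "season_id"]
        obs = self.model.observations[self.model.observations["season_id"].isin(year_ids)]
        tot_y = totals[totals["season_id"].isin(year_ids)]
        by_st_y = by_station[by_station["season_id"].isin(year_ids)]

        crop_of = seasons.set_index("season_id")["crop"]
        beta_by_season = {sid: econ.beta(crop_of[sid]) for sid in year_ids}
        state_tab = dmg.state_output_table(tot_y, obs, self.model.output, beta_by_season)
        state_tab["crop"] = state_tab["season_id"].map(crop_of)
        state_tab["usd_lost"] = [
            t * econ.price(c) for t, c in zip(state_tab["tons_lost"], state_tab["crop"])
        ]
        station_tab = dmg.station_damage_table(
            by_st_y, obs, self.model.output, seasons, econ, beta_no2_by_season=beta_by_season
        )
        intens = dmg.intensity_table(station_tab, self.model.generation, seasons, year)
        return {"state": state_tab, "station": station_tab, "intensity": intens, "year": year}

    def bootstrap(
        self,
        config: BootstrapConfig,
        target_year: int | None = None,
    ) -> dict:
        """Cluster-bootstrap prediction intervals for one season type."""
        if self.model.output is None:
            raise ValueError("bootstrap quantities require the state output table")
        return bootstrap_run(
            self.model.observations,
            self.model.exposures,
            self.model.per_station_exposures,
            self.model.seasons,
            self.model.output,
            self.model.econ,
            config,
            target_year=target_year,
        )

    def station_ledger(
        self,
        year: int | None = None,
        bootstrap_results: dict | None = None,
    ):
        """Assemble the per-station ledger used by the policy stage.

        ``bootstrap_results`` maps season type -> bootstrap_run output; when
        absent, crop damage bounds collapse to the point estimates.
        Returns (ledger, seasonal_units).
        """
        if self.model.mortality is None:
            raise ValueError("station ledger requires the mortality table")
        seasons = self.model.seasons
        if year is None:
            year = int(seasons["year"].max())
        tabs = self.damages(year=year)
        station_tab, intens = tabs["station"], tabs["intensity"]
        year_ids = seasons.loc[seasons["year"] == year, "season_id"]

        ann = intens[intens["season_id"] == f"annual_{year}"][
            ["station_id", "usd_lost", "generation_gwh", "intensity_usd_per_gwh"]
        ].rename(
            columns={
                "usd_lost": "crop_usd",
                "generation_gwh": "annual_generation_gwh",
                "intensity_usd_per_gwh": "crop_intensity_annual",
            }
        )
        ledger = ann.merge(self.model.mortality, on="station_id", how="left")
        ledger = ledger.rename(columns={"deaths_per_gwh": "mortality_intensity"})
        ledger["mortality_usd"] = (
            ledger["mortality_intensity"] * ledger["annual_generation_gwh"] * self.model.econ.vsl
        )

        lo, hi = self._station_crop_bounds(bootstrap_results, year_ids)
        ledger["crop_usd_lo"] = ledger["station_id"].map(lo).fillna(ledger["crop_usd"])
        ledger["crop_usd_hi"] = ledger["station_id"].map(hi).fillna(ledger["crop_usd"])

        seasonal = intens[intens["season_id"].isin(year_ids)].rename(
            columns={
                "usd_lost": "crop_usd",
                "generation_gwh": "seasonal_generation_gwh",
                "intensity_usd_per_gwh": "crop_intensity",
            }
        )[["station_id", "season_id", "crop", "seasonal_generation_gwh", "crop_intensity", "crop_usd"]]
        slo, shi = self._station_crop_bounds(bootstrap_results, year_ids, per_season=True)
        key = list(zip(seasonal["station_id"], seasonal["season_id"]))
        seasonal["crop_usd_lo"] = [slo.get(k, c) for k, c in zip(key, seasonal["crop_usd"])]
        seasonal["crop_usd_hi"] = [shi.get(k, c) for k, c in zip(key, seasonal["crop_usd"])]
        return ledger, seasonal.reset_index(drop=True)

    def _station_crop_bounds(self, bootstrap_results, year_ids, per_season=False):
        lo, hi = {}, {}
        if bootstrap_results is None:
            return lo, hi
        for res in bootstrap_results.values():
            br = res.get("station_damage_usd")
            if br is None:
                continue
            frame = br.to_frame()
            frame = frame[frame["season_id"].isin(set(year_ids))]
            for _, r in frame.iterrows():
                k = (r["station_id"], r["season_id"]) if per_season else r["station_id"]
                lo[k] = lo.get(k, 0.0) + r["lo"]
                hi[k] = hi.get(k, 0.0) + r["hi"]
        return lo, hi

    def scenario(
        self,
        objective: str,
        budget_fraction: float = 0.10,
        year: int | None = None,
        bootstrap_results: dict | None = None,
    ) -> PolicyScenario:
        """Rank-and-cut emissions-reduction scenario for one objective."""
        ledger, seasonal = self.station_ledger(year=year, bootstrap_results=bootstrap_results)
        if objective == "combined_seasonal":
            return seasonal_selection(
                ledger, seasonal, budget_fraction=budget_fraction, vsl=self.model.econ.vsl
            )
        return rank_and_select(
            ledger, objective, budget_fraction=budget_fraction, vsl=self.model.econ.vsl
        )
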