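"""Translation of attributable NO2 into crop and mortality damages.

The chain is: attributable NO2 -> fractional yield change via the NIRv
greenness proxy (externally estimated NO2->NIRv coefficients, a 0.007
bare-soil NIRv baseline) -> state output gains in tons scaled by reported
state output -> station-level damages via the per-station attribution
decomposition -> monetization (rice US$600/ton, wheat US$350/ton) and
damage intensities in USD per GWh of generation. Mortality is monetized
at a value of statistical life of US$120,000 per death.

Points whose NIRv does not exceed the bare-soil baseline are excluded from
yield arithmetic (the denominator would be nonpositive); exclusions are
counted and logged, never silently fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NIRV_BASELINE = 0.007


@dataclass
class EconomicParams:
    """Prices, VSL and the NO2->NIRv exposure-response coefficients."""

    price_rice: float = 600.0  # USD/ton
    price_wheat: float = 350.0  # USD/ton
    vsl: float = 120000.0  # USD/death
    beta_no2_rice: float = 0.0006  # NIRv per umol/m2
    beta_no2_rice_se: float = 0.0001
    beta_no2_wheat: float = 0.0007
    beta_no2_wheat_se: float = 0.0002
    nirv_baseline: float = NIRV_BASELINE

    def __post_init__(self):
        if min(self.price_rice, self.price_wheat, self.vsl) <= 0:
            raise ValueError("prices and VSL must be positive")
        if min(self.beta_no2_rice_se, self.beta_no2_wheat_se) < 0:
            raise ValueError("coefficient SEs must be nonnegative")

    def price(self, crop: str) -> float:
        return {"rice": self.price_rice, "wheat": self.price_wheat}[crop]

    def beta(self, crop: str) -> float:
        return {"rice": self.beta_no2_rice, "wheat": self.beta_no2_wheat}[crop]

    def beta_se(self, crop: str) -> float:
        return {"rice": self.beta_no2_rice_se, "wheat": self.beta_no2_wheat_se}[crop]


def yield_change(nirv, coal_no2, beta_no2, baseline: float = NIRV_BASELINE):
    """Fractional yield change from eliminating attributable NO2.

    (NIRv + Coal*beta - b) / (NIRv - b) - 1, with b the bare-soil NIRv
    baseline. Returns NaN (with a logged count) where NIRv <= b.
    """
    nirv = np.asarray(nirv, float)
    coal = np.asarray(coal_no2, float)
    denom = nirv - baseline
    bad = denom <= 0
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        logger.warning("yield_change: excluded %d points with NIRv <= %.3f", n_bad, baseline)
    out = np.where(bad, np.nan, (coal * beta_no2) / np.where(bad, np.nan, denom))
    return float(out) if out.ndim == 0 else out


def _merged_obs(observations: pd.DataFrame, attributions: pd.DataFrame, keys) -> pd.DataFrame:
    """Observation rows with an attribution column (zero where absent)."""
    out = observations.merge(attributions, on=keys, how="left")
    acol = [c for c in attributions.columns if c not in keys]
    out[acol] = out[acol].fillna(0.0)
    return out


def state_output_gain(
    state: str,
    season_id: str,
    attributions: pd.DataFrame,
    observations: pd.DataFrame,
    beta_no2: float,
    outputs: pd.DataFrame,
    baseline: float = NIRV_BASELINE,
) -> float:
    """Tons of output gained in one state-season (scalar convenience form).

    ``observations`` needs point_id, season_id, state, nirv, crop_fraction;
    ``attributions`` needs point_id, season_id, coal_no2_total.
    """
    tab = state_output_table(
        attributions,
        observations,
        outputs,
        beta_no2_by_season={season_id: beta_no2},
        baseline=baseline,
    )
    row = tab[(tab["state"] == state) & (tab["season_id"] == season_id)]
    if row.empty:
        raise KeyError(f"state {state!r} absent from outputs for season {season_id!r}")
    return float(row["tons_lost"].iloc[0])


def state_output_table(
    attributions: pd.DataFrame,
    observations: pd.DataFrame,
    outputs: pd.DataFrame,
    beta_no2_by_season: dict,
    baseline: float = NIRV_BASELINE,
) -> pd.DataFrame:
    """Output gains in tons per state x season.

    Numerator: cropfrac-weighted sum of attributable NO2 x beta over the
    state's points; denominator: cropfrac-weighted sum of (NIRv - baseline)
    over ALL the state's cropland points (not just those within 100 km),
    excluding NIRv <= baseline points from both sums.
    """
    obs = _merged_obs(
        observations, attributions[["point_id", "season_id", "coal_no2_total"]],
        ["point_id", "season_id"],
    )
    obs = obs[obs["season_id"].isin(beta_no2_by_season)]
    denom_ok = obs["nirv"] > baseline
    n_bad = int((~denom_ok).sum())
    if n_bad:
        logger.warning("state_output_table: excluded %d NIRv<=baseline rows", n_bad)
    obs = obs[denom_ok].copy()
    beta = obs["season_id"].map(beta_no2_by_season)
    obs["num"] = obs["coal_no2_total"] * beta * obs["crop_fraction"]
    obs["den"] = (obs["nirv"] - baseline) * obs["crop_fraction"]
    agg = obs.groupby(["state", "season_id"], as_index=False)[["num", "den"]].sum()
    merged = agg.merge(outputs, on=["state", "season_id"], how="left")
    if merged["output_tons"].isna().any():
        missing = merged.loc[merged["output_tons"].isna(), ["state", "season_id"]]
        raise KeyError(f"states missing from output table: {missing.to_dict('records')}")
    merged["tons_lost"] = merged["output_tons"] * merged["num"] / merged["den"]
    return merged[["state", "season_id", "tons_lost"]]


def station_damage_table(
    per_station_attributions: pd.DataFrame,
    observations: pd.DataFrame,
    outputs: pd.DataFrame,
    seasons: pd.DataFrame,
    econ: EconomicParams,
    beta_no2_by_season: dict | None = None,
    baseline: float = NIRV_BASELINE,
) -> pd.DataFrame:
    """Station-level tons lost and USD per season, summed across states.

    Uses the per-station attribution decomposition, so station damages sum
    exactly to the state totals within each season (cross-border effects
    included).
    """
    crop_of = seasons.set_index("season_id")["crop"]
    if beta_no2_by_season is None:
        beta_no2_by_season = {sid: econ.beta(c) for sid, c in crop_of.items()}
    obs = observations.merge(
        per_station_attributions[["point_id", "season_id", "station_id", "coal_no2"]],
        on=["point_id", "season_id"],
        how="inner",
    )
    obs = obs[obs["nirv"] > baseline].copy()
    beta = obs["season_id"].map(beta_no2_by_season)
    obs["num"] = obs["coal_no2"] * beta * obs["crop_fraction"]
    num = obs.groupby(["state", "season_id", "station_id"], as_index=False)["num"].sum()

    # state-season denominators over all cropland points
    den_obs = observations[observations["nirv"] > baseline].copy()
    den_obs["den"] = (den_obs["nirv"] - baseline) * den_obs["crop_fraction"]
    den = den_obs.groupby(["state", "season_id"], as_index=False)["den"].sum()

    m = num.merge(den, on=["state", "season_id"], how="left").merge(
        outputs, on=["state", "season_id"], how="left"
    )
    if m["output_tons"].isna().any():
        missing = m.loc[m["output_tons"].isna(), ["state", "season_id"]].drop_duplicates()
        raise KeyError(f"states missing from output table: {missing.to_dict('records')}")
    m["tons"] = m["output_tons"] * m["num"] / m["den"]
    per_station = m.groupby(["station_id", "season_id"], as_index=False)["tons"].sum()
    per_station = per_station.rename(columns={"tons": "tons_lost"})
    per_station["crop"] = per_station["season_id"].map(crop_of)
    per_station["usd_lost"] = per_station.apply(
        lambda r: r["tons_lost"] * econ.price(r["crop"]), axis=1
    )
    return per_station[["station_id", "season_id", "crop", "tons_lost", "usd_lost"]]


def seasonal_generation(generation: pd.DataFrame, seasons: pd.DataFrame) -> pd.DataFrame:
    """Total GWh per station x season."""
    gen = generation.copy()
    gen["date"] = pd.to_datetime(gen["date"])
    parts = []
    for _, s in seasons.iterrows():
        span = gen[
            (gen["date"] >= pd.Timestamp(s["start_date"]))
            & (gen["date"] <= pd.Timestamp(s["end_date"]))
        ]
        tot = span.groupby("station_id", as_index=False)["generation_gwh"].sum()
        tot["season_id"] = s["season_id"]
        parts.append(tot)
    return pd.concat(parts, ignore_index=True)[["station_id", "season_id", "generation_gwh"]]


def annual_generation(generation: pd.DataFrame, seasons: pd.DataFrame, year: int) -> pd.DataFrame:
    """Total recorded GWh per station over a calendar year's seasons."""
    sg = seasonal_generation(generation, seasons)
    year_ids = seasons.loc[seasons["year"] == year, "season_id"]
    return (
        sg[sg["season_id"].isin(year_ids)]
        .groupby("station_id", as_index=False)["generation_gwh"]
        .sum()
    )


def damage_intensity(usd_lost: float, generation_gwh: float) -> float:
    """USD of damage per GWh generated; undefined for zero generation."""
    if generation_gwh <= 0:
        raise ZeroDivisionError("damage intensity undefined for nonpositive generation")
    return usd_lost / generation_gwh


def intensity_table(
    station_damages: pd.DataFrame,
    generation: pd.DataFrame,
    seasons: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Seasonal and annual USD/GWh damage intensities per station for one year.

    Seasonal intensity divides each crop season's damages by that season's
    generation; annual intensity divides combined rice+wheat damages by the
    year's total recorded generation. Stations with zero generation in a
    period are flagged (intensity NaN), not fabricated.
    """
    year_ids = set(seasons.loc[seasons["year"] == year, "season_id"])
    dmg = station_damages[station_damages["season_id"].isin(year_ids)]
    sg = seasonal_generation(generation, seasons)
    seas = dmg.merge(sg, on=["station_id", "season_id"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        seas["intensity_usd_per_gwh"] = np.where(
            seas["generation_gwh"] > 0, seas["usd_lost"] / seas["generation_gwh"], np.nan
        )
    n_flag = int(seas["intensity_usd_per_gwh"].isna().sum())
    if n_flag:
        logger.warning("intensity_table: %d station-seasons with zero generation", n_flag)

    ann_dmg = dmg.groupby("station_id", as_index=False)["usd_lost"].sum()
    ann_gen = annual_generation(generation, seasons, year)
    ann = ann_dmg.merge(ann_gen, on="station_id", how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        ann["intensity_usd_per_gwh"] = np.where(
            ann["generation_gwh"] > 0, ann["usd_lost"] / ann["generation_gwh"], np.nan
        )
    ann.insert(1, "season_id", f"annual_{year}")
    ann.insert(2, "crop", "combined")
    cols = ["station_id", "season_id", "crop", "usd_lost", "generation_gwh", "intensity_usd_per_gwh"]
    seas = seas[cols]
    return pd.concat([seas, ann[cols]], ignore_index=True)


def monetize_mortality(deaths_per_gwh: float, vsl: float) -> float:
    """Mortality damage intensity in USD/GWh."""
    if deaths_per_gwh < 0:
        raise ValueError("deaths_per_gwh must be nonnegative")
    return deaths_per_gwh * vsl
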