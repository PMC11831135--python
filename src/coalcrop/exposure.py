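"""Directional exposure construction.

Converts station locations, daily wind-from octants and daily generation
into the five seasonal exposure regressors (upwind, almost-upwind,
crosswind, almost-downwind, downwind GWh) per cropland point x season x
10-km distance band, together with the single-station eligibility filter
used to limit confounding.

Conventions
-----------
* Wind octants denote the direction the wind blows FROM (meteorological).
  A station due north of a point, on a day with northerly wind at the
  station, delivers *upwind* generation to the point.
* Octant windows are 45 degrees wide, half-open and closed clockwise at the
  lower edge: octant k covers [45k - 22.5, 45k + 22.5) degrees.
* Distance bands are half-open [10k, 10(k+1)) km; stations at exactly
  100.0 km contribute nothing.
* Bearings are great-circle initial bearings on a sphere of radius
  6371.0088 km, measured clockwise from true north.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

OCTANTS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
OCTANT_INDEX = {label: i for i, label in enumerate(OCTANTS)}

CATEGORIES = ("upwind", "almost_upwind", "crosswind", "almost_downwind", "downwind")
CATEGORY_INDEX = {label: i for i, label in enumerate(CATEGORIES)}

#: column names of the five exposure regressors, in category order
EXPOSURE_COLUMNS = ("gen_up", "gen_almost_up", "gen_cross", "gen_almost_down", "gen_down")

N_BANDS = 10
BAND_WIDTH_KM = 10.0
MAX_DISTANCE_KM = 100.0


@dataclass(frozen=True)
class Octant:
    label: str

    def __post_init__(self):
        if self.label not in OCTANT_INDEX:
            raise ValueError(f"unknown octant {self.label!r}")

    @property
    def index(self) -> int:
        return OCTANT_INDEX[self.label]

    @property
    def center_deg(self) -> float:
        return 45.0 * self.index


@dataclass(frozen=True)
class DirectionCategory:
    label: str

    def __post_init__(self):
        if self.label not in CATEGORY_INDEX:
            raise ValueError(f"unknown direction category {self.label!r}")

    @property
    def octant_offset(self) -> int:
        return CATEGORY_INDEX[self.label]


@dataclass(frozen=True)
class DistanceBand:
    """One of the ten 10-km rings [lo_km, hi_km) out to 100 km."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index < N_BANDS:
            raise ValueError(f"band index must be in 0..{N_BANDS - 1}, got {self.index}")

    @property
    def lo_km(self) -> float:
        return BAND_WIDTH_KM * self.index

    @property
    def hi_km(self) -> float:
        return BAND_WIDTH_KM * (self.index + 1)


def _check_coords(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
        raise ValueError("coordinates out of range: lat in [-90,90], lon in [-180,180]")
    return lat, lon


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between WGS84 decimal-degree points.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1 = _check_coords(lat1, lon1)
    lat2, lon2 = _check_coords(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360).

    Measured clockwise from true north. Identical points have no bearing.
    """
    lat1, lon1 = _check_coords(lat1, lon1)
    lat2, lon2 = _check_coords(lat2, lon2)
    if np.any((lat1 == lat2) & (lon1 == lon2)):
        raise ValueError("bearing undefined for identical points")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2) - np.radians(lon1)
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def octant_of(bearing_deg):
    """Octant index (0=N .. 7=NW) containing a bearing in [0, 360).

    Windows are [center - 22.5, center + 22.5); a bearing exactly on the
    shared edge is assigned clockwise (22.5 -> NE, 337.5 -> N).
    """
    b = np.asarray(bearing_deg, dtype=float)
    if np.any((b < 0) | (b >= 360)):
        raise ValueError("bearing must be in [0, 360)")
    idx = (np.floor(np.mod(b + 22.5, 360.0) / 45.0)).astype(int)
    return idx if idx.ndim else int(idx)


def octant_offset(i, j):
    """Circular distance between octant indices i and j (0..4)."""
    d = np.mod(np.asarray(i) - np.asarray(j), 8)
    return np.minimum(d, 8 - d)


def direction_category(bearing_octant, wind_from_octant):
    """Classify a wind octant relative to the point->station bearing octant.

    Offset 0 (wind from the station's direction) is upwind, 4 (opposite)
    is downwind; accepts octant labels, indices or Octant objects.
    """
    i = _octant_index(bearing_octant)
    j = _octant_index(wind_from_octant)
    return CATEGORIES[int(octant_offset(i, j))]


def _octant_index(o) -> int:
    if isinstance(o, Octant):
        return o.index
    if isinstance(o, str):
        return OCTANT_INDEX[o]
    return int(o)


# 8x8 table: OFFSET_TABLE[bearing_octant, wind_octant] -> category index 0..4
OFFSET_TABLE = octant_offset(np.arange(8)[:, None], np.arange(8)[None, :])


def station_direction_totals(
    generation: pd.DataFrame,
    wind: pd.DataFrame,
    seasons: pd.DataFrame,
) -> pd.DataFrame:
    """Seasonal generation totals per station x season x wind-from octant.

    Parameters
    ----------
    generation : columns station_id, date, generation_gwh (daily)
    wind : columns station_id, date, wind_from_octant (daily)
    seasons : columns season_id, start_date, end_date

    Returns a frame with columns station_id, season_id and one GWh column
    per octant label. Every station must have a wind and a generation
    record for every day of every season.
    """
    gen = generation.copy()
    gen["date"] = pd.to_datetime(gen["date"])
    wnd = wind.copy()
    wnd["date"] = pd.to_datetime(wnd["date"])
    daily = gen.merge(wnd, on=["station_id", "date"], how="outer", indicator=True)

    stations = daily["station_id"].unique()
    pieces = []
    for _, srow in seasons.iterrows():
        start = pd.Timestamp(srow["start_date"])
        end = pd.Timestamp(srow["end_date"])
        n_days = (end - start).days + 1
        span = daily[(daily["date"] >= start) & (daily["date"] <= end)]
        counts = span.groupby("station_id").agg(
            n=("date", "size"), ok=("_merge", lambda m: (m == "both").all())
        )
        bad = [
            s
            for s in stations
            if s not in counts.index or counts.loc[s, "n"] != n_days or not counts.loc[s, "ok"]
        ]
        if bad:
            raise ValueError(
                f"incomplete daily wind/generation coverage for season "
                f"{srow['season_id']!r} at stations {sorted(bad)}"
            )
        tot = (
            span.pivot_table(
                index="station_id",
                columns="wind_from_octant",
                values="generation_gwh",
                aggfunc="sum",
                fill_value=0.0,
            )
            .reindex(columns=list(OCTANTS), fill_value=0.0)
            .reset_index()
        )
        tot.insert(1, "season_id", srow["season_id"])
        pieces.append(tot)
    out = pd.concat(pieces, ignore_index=True)
    out.columns.name = None
    return out


def pair_geometry(points: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Point-station pairs within 100 km: band index and bearing octant.

    The fleet is assumed fixed over the analysis period, so this geometry
    (and the per-band station counts derived from it) is time-invariant.
    """
    plat = points["lat"].to_numpy(float)
    plon = points["lon"].to_numpy(float)
    slat = stations["lat"].to_numpy(float)
    slon = stations["lon"].to_numpy(float)
    d = haversine_km(plat[:, None], plon[:, None], slat[None, :], slon[None, :])
    ii, jj = np.nonzero(d < MAX_DISTANCE_KM)
    if len(ii) == 0:
        return pd.DataFrame(
            columns=["point_id", "station_id", "band_index", "bearing_octant"]
        )
    bearing = initial_bearing_deg(plat[ii], plon[ii], slat[jj], slon[jj])
    return pd.DataFrame(
        {
            "point_id": points["point_id"].to_numpy()[ii],
            "station_id": stations["station_id"].to_numpy()[jj],
            "band_index": (d[ii, jj] // BAND_WIDTH_KM).astype(int),
            "bearing_octant": octant_of(bearing),
        }
    )


def band_station_counts(pairs: pd.DataFrame) -> pd.DataFrame:
    """Number of stations per (point_id, band_index), from pair_geometry."""
    return (
        pairs.groupby(["point_id", "band_index"], as_index=False)
        .agg(n_stations_in_band=("station_id", "nunique"))
    )


def build_exposure(
    points: pd.DataFrame,
    stations: pd.DataFrame,
    direction_totals: pd.DataFrame,
    *,
    per_station: bool = False,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Five directional seasonal exposure regressors per point x season x band.

    Each in-band station's eight octant generation totals are mapped to the
    five categories through the circular offset between the point->station
    bearing octant and each wind-from octant, then summed over stations.
    Stations beyond 100 km contribute nothing.

    With ``per_station=True`` the station sum is not taken and a long table
    with a ``station_id`` column is returned (used for the per-station
    attribution decomposition).

    Only (point, season, band) rows with at least one in-band station are
    returned; absent rows mean zero exposure and ``n_stations_in_band`` = 0.
    """
    if pairs is None:
        pairs = pair_geometry(points, stations)
    season_ids = direction_totals["season_id"].unique()
    if len(pairs) == 0:
        cols = ["point_id", "season_id", "band_index"]
        if per_station:
            cols.insert(1, "station_id")
        return pd.DataFrame(
            columns=cols + list(EXPOSURE_COLUMNS) + ["n_stations_in_band"]
        )

    merged = pairs.merge(direction_totals, on="station_id", how="inner")
    octant_totals = merged[list(OCTANTS)].to_numpy(float)  # (rows, 8)
    b = merged["bearing_octant"].to_numpy(int)
    cat_of_wind = OFFSET_TABLE[b]  # (rows, 8) category index per wind octant
    five = np.zeros((len(merged), 5))
    for w in range(8):
        np.add.at(five, (np.arange(len(merged)), cat_of_wind[:, w]), octant_totals[:, w])
    exp_long = merged[["point_id", "station_id", "season_id", "band_index"]].copy()
    for c, col in enumerate(EXPOSURE_COLUMNS):
        exp_long[col] = five[:, c]

    counts = band_station_counts(pairs)
    if per_station:
        out = exp_long.merge(counts, on=["point_id", "band_index"], how="left")
        return out.sort_values(["point_id", "season_id", "band_index", "station_id"]).reset_index(
            drop=True
        )
    agg = (
        exp_long.groupby(["point_id", "season_id", "band_index"], as_index=False)[
            list(EXPOSURE_COLUMNS)
        ].sum()
    )
    out = agg.merge(counts, on=["point_id", "band_index"], how="left")
    assert set(out["season_id"]) <= set(season_ids)
    return out.sort_values(["point_id", "season_id", "band_index"]).reset_index(drop=True)


def single_station_mask(exposures: pd.DataFrame, band: int) -> pd.DataFrame:
    """Eligibility flag per point x season for one band's regression.

    A point is eligible at a distance band iff exactly one station lies in
    that band (the single-station confounding filter). Station counts are
    time-invariant for a fixed fleet, so the flag is constant over seasons.
    """
    sub = exposures[exposures["band_index"] == band]
    out = sub[["point_id", "season_id"]].copy()
    out["eligible"] = (sub["n_stations_in_band"] == 1).to_numpy()
    return out.reset_index(drop=True)
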