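"""Geometry, octant classification and exposure bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalcrop.exposure import (
    CATEGORIES,
    EXPOSURE_COLUMNS,
    OCTANTS,
    DistanceBand,
    Octant,
    build_exposure,
    direction_category,
    haversine_km,
    initial_bearing_deg,
    octant_of,
    pair_geometry,
    single_station_mask,
    station_direction_totals,
)

EARTH_RADIUS_KM = 6371.0088


def brute_bearing(lat1, lon1, lat2, lon2):
    """Independent bearing oracle via tangent-plane projection on the sphere."""

    def unit(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

    p1, p2 = unit(lat1, lon1), unit(lat2, lon2)
    north_pole = np.array([0.0, 0.0, 1.0])
    t = p2 - np.dot(p2, p1) * p1
    north = north_pole - np.dot(north_pole, p1) * p1
    east = np.cross(north_pole, p1)
    ang = np.degrees(np.arctan2(np.dot(t, east / np.linalg.norm(east)),
                                np.dot(t, north / np.linalg.norm(north))))
    return ang % 360.0


class TestHaversine:
    def test_identity_and_symmetry(self):
        assert haversine_km(12.0, 77.0, 12.0, 77.0) == 0.0
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.uniform([-60, -179], [60, 179])
            b = rng.uniform([-60, -179], [60, 179])
            d1 = haversine_km(a[0], a[1], b[0], b[1])
            d2 = haversine_km(b[0], b[1], a[0], a[1])
            assert d1 == pytest.approx(d2, rel=1e-12)
            assert d1 >= 0

    def test_equatorial_degree(self):
        # one degree of longitude at the equator is an exact arc
        expected = 2 * np.pi * EARTH_RADIUS_KM / 360.0
        assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(expected, rel=1e-10)

    def test_out_of_range_coordinates(self):
        with pytest.raises(ValueError):
            haversine_km(95.0, 0.0, 0.0, 0.0)


class TestBearing:
    def test_axis_cases(self):
        assert initial_bearing_deg(0.0, 0.0, 1.0, 0.0) == pytest.approx(0.0, abs=1e-9)
        assert initial_bearing_deg(0.0, 0.0, 0.0, 1.0) == pytest.approx(90.0, abs=1e-9)

    def test_matches_spherical_trig_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            lat1, lon1 = rng.uniform(-60, 60), rng.uniform(-179, 179)
            lat2, lon2 = rng.uniform(-60, 60), rng.uniform(-179, 179)
            got = initial_bearing_deg(lat1, lon1, lat2, lon2)
            want = brute_bearing(lat1, lon1, lat2, lon2)
            diff = min(abs(got - want), 360 - abs(got - want))
            assert diff < 1e-6

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            initial_bearing_deg(10.0, 70.0, 10.0, 70.0)


class TestOctants:
    @pytest.mark.parametrize(
        "bearing,label",
        [(0.0, "N"), (22.5, "NE"), (337.5, "N"), (337.49, "NW"), (90.0, "E"), (180.0, "S")],
    )
    def test_boundary_convention(self, bearing, label):
        assert OCTANTS[octant_of(bearing)] == label

    def test_octant_dataclass(self):
        assert Octant("NE").center_deg == 45.0
        with pytest.raises(ValueError):
            Octant("NNE")

    def test_distance_band_bounds(self):
        b = DistanceBand(3)
        assert (b.lo_km, b.hi_km) == (30.0, 40.0)
        with pytest.raises(ValueError):
            DistanceBand(10)


class TestDirectionCategory:
    @pytest.mark.parametrize(
        "bearing,wind,cat",
        [
            ("N", "N", "upwind"),
            ("N", "NE", "almost_upwind"),
            ("N", "NW", "almost_upwind"),
            ("N", "E", "crosswind"),
            ("N", "W", "crosswind"),
            ("N", "SE", "almost_downwind"),
            ("N", "S", "downwind"),
        ],
    )
    def test_station_north_worked_example(self, bearing, wind, cat):
        assert direction_category(bearing, wind) == cat

    def test_offset_symmetry(self):
        for i in OCTANTS:
            for j in OCTANTS:
                assert direction_category(i, j) == direction_category(j, i)

    def test_brute_force_enumeration(self):
        # scan all integer bearings x 8 winds against a from-scratch classifier
        for bearing in range(360):
            oct_idx = int(((bearing + 22.5) % 360) // 45)
            for wind in range(8):
                d = abs(oct_idx - wind) % 8
                offset = min(d, 8 - d)
                assert direction_category(octant_of(float(bearing)), wind) == CATEGORIES[offset]


class TestGeometryProperties:
    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        lat1=st.floats(-60, 60), lon1=st.floats(-179, 179),
        lat2=st.floats(-60, 60), lon2=st.floats(-179, 179),
    )
    def test_distance_symmetric_nonnegative(self, lat1, lon1, lat2, lon2):
        d = haversine_km(lat1, lon1, lat2, lon2)
        assert d >= 0
        assert d == pytest.approx(haversine_km(lat2, lon2, lat1, lon1), abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(bearing=st.floats(0, 360, exclude_max=True))
    def test_octant_window_contains_bearing(self, bearing):
        idx = octant_of(bearing)
        center = 45.0 * idx
        # signed angular distance from the window center is within the
        # half-open 45-degree window
        delta = (bearing - center + 180.0) % 360.0 - 180.0
        assert -22.5 <= delta < 22.5


def _series(station, dates, gens, winds):
    gen = pd.DataFrame({"station_id": station, "date": dates, "generation_gwh": gens})
    wnd = pd.DataFrame({"station_id": station, "date": dates, "wind_from_octant": winds})
    return gen, wnd


def _one_season(season_id="monsoon_2019", start="2019-09-01", end="2019-10-31"):
    return pd.DataFrame(
        {"season_id": [season_id], "crop": ["rice"], "year": [2019],
         "start_date": [start], "end_date": [end]}
    )


class TestDirectionTotals:
    def test_three_day_hand_sum(self):
        seasons = pd.DataFrame(
            {"season_id": ["s"], "crop": ["rice"], "year": [2019],
             "start_date": ["2019-09-01"], "end_date": ["2019-09-03"]}
        )
        gen, wnd = _series("a", ["2019-09-01", "2019-09-02", "2019-09-03"],
                           [10.0, 20.0, 30.0], ["N", "N", "E"])
        tot = station_direction_totals(gen, wnd, seasons)
        assert tot.loc[0, "N"] == 30.0
        assert tot.loc[0, "E"] == 30.0
        assert tot[[o for o in OCTANTS if o not in ("N", "E")]].to_numpy().sum() == 0.0

    def test_all_zero_generation(self):
        seasons = pd.DataFrame(
            {"season_id": ["s"], "crop": ["rice"], "year": [2019],
             "start_date": ["2019-09-01"], "end_date": ["2019-09-02"]}
        )
        gen, wnd = _series("a", ["2019-09-01", "2019-09-02"], [0.0, 0.0], ["N", "S"])
        tot = station_direction_totals(gen, wnd, seasons)
        assert tot[list(OCTANTS)].to_numpy().sum() == 0.0

    def test_conservation_random_season(self):
        rng = np.random.default_rng(2)
        dates = pd.date_range("2019-09-01", "2019-10-31")
        gens = rng.uniform(0, 20, len(dates))
        winds = rng.choice(list(OCTANTS), len(dates))
        gen, wnd = _series("a", dates, gens, winds)
        tot = station_direction_totals(gen, wnd, _one_season())
        # brute force: sum per octant by scanning days
        for o in OCTANTS:
            assert tot.loc[0, o] == pytest.approx(gens[winds == o].sum(), rel=1e-12)
        assert tot[list(OCTANTS)].to_numpy().sum() == pytest.approx(gens.sum(), rel=1e-12)

    def test_missing_day_rejected(self):
        gen, wnd = _series("a", ["2019-09-01"], [5.0], ["N"])
        with pytest.raises(ValueError, match="incomplete"):
            station_direction_totals(gen, wnd, _one_season())


def _station_table(rows):
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon"])


class TestBuildExposure:
    def setup_method(self):
        # one point at origin, one station ~55 km due north
        self.points = pd.DataFrame(
            {"point_id": ["p"], "lat": [20.0], "lon": [80.0]}
        )
        self.stations = _station_table([("a", 20.5, 80.0)])
        self.totals = pd.DataFrame(
            [{"station_id": "a", "season_id": "s", **{o: 0.0 for o in OCTANTS}}]
        )

    def test_single_station_north(self):
        self.totals.loc[0, "N"] = 30.0
        self.totals.loc[0, "E"] = 30.0
        exp = build_exposure(self.points, self.stations, self.totals)
        assert len(exp) == 1
        row = exp.iloc[0]
        assert row["band_index"] == 5  # ~55.6 km
        assert row["gen_up"] == 30.0  # N wind, bearing N -> upwind
        assert row["gen_cross"] == 30.0  # E wind two octants away -> crosswind
        assert row["n_stations_in_band"] == 1

    def test_no_station_in_range(self):
        far = _station_table([("a", 25.0, 80.0)])  # ~550 km away
        exp = build_exposure(self.points, far, self.totals)
        assert exp.empty  # absent rows mean zero exposure, count 0

    def test_colocated_station_doubles(self):
        self.totals.loc[0, "N"] = 30.0
        two = _station_table([("a", 20.5, 80.0), ("b", 20.5, 80.0)])
        tot2 = pd.concat(
            [self.totals, self.totals.assign(station_id="b")], ignore_index=True
        )
        one = build_exposure(self.points, self.stations, self.totals)
        both = build_exposure(self.points, two, tot2)
        assert both.iloc[0]["gen_up"] == 2 * one.iloc[0]["gen_up"]
        assert both.iloc[0]["n_stations_in_band"] == 2

    def test_additive_in_stations(self, small_world):
        w = small_world
        from coalcrop.exposure import build_exposure as be

        totals = station_direction_totals(w.generation, w.wind, w.seasons)
        full = be(w.points, w.stations, totals)
        half1 = w.stations.iloc[: len(w.stations) // 2]
        half2 = w.stations.iloc[len(w.stations) // 2 :]
        e1 = be(w.points, half1, totals[totals["station_id"].isin(half1["station_id"])])
        e2 = be(w.points, half2, totals[totals["station_id"].isin(half2["station_id"])])
        cols = list(EXPOSURE_COLUMNS)
        merged = (
            pd.concat([e1, e2])
            .groupby(["point_id", "season_id", "band_index"], as_index=False)[cols]
            .sum()
        )
        joined = full.merge(merged, on=["point_id", "season_id", "band_index"],
                            suffixes=("", "_sum"))
        assert len(joined) == len(full)
        for c in cols:
            np.testing.assert_allclose(joined[c], joined[c + "_sum"], rtol=1e-12)


class TestSingleStationMask:
    def test_counts(self):
        exp = pd.DataFrame(
            {
                "point_id": ["p1", "p2", "p3"],
                "season_id": ["s"] * 3,
                "band_index": [2, 2, 2],
                "n_stations_in_band": [1, 2, 0],
            }
        )
        mask = single_station_mask(exp, band=2)
        assert mask.set_index("point_id")["eligible"].to_dict() == {
            "p1": True, "p2": False, "p3": False,
        }


class TestConservation:
    def test_category_totals_sum_to_in_band_generation(self, small_world):
        """Five category totals must sum to the seasonal generation of the
        stations in the band, for every point x season x band."""
        w = small_world
        totals = station_direction_totals(w.generation, w.wind, w.seasons)
        pairs = pair_geometry(w.points, w.stations)
        exp = build_exposure(w.points, w.stations, totals, pairs=pairs)
        season_sum = totals.set_index(["station_id", "season_id"])[list(OCTANTS)].sum(axis=1)
        in_band = pairs.merge(
            season_sum.rename("gwh").reset_index(), on="station_id"
        ).groupby(["point_id", "season_id", "band_index"])["gwh"].sum()
        cat_sum = exp.set_index(["point_id", "season_id", "band_index"])[
            list(EXPOSURE_COLUMNS)
        ].sum(axis=1)
        aligned, expected = cat_sum.align(in_band, join="left")
        np.testing.assert_allclose(aligned.to_numpy(), expected.to_numpy(), rtol=1e-9)
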