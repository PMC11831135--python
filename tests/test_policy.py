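"""Greedy rank-and-cut selection and benefit accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coalcrop.policy import (
    benefit_range,
    rank_and_select,
    scenario_benefits,
    seasonal_selection,
)

VSL = 120000.0


def make_ledger(intensities, generations, crop_intensities=None, crop_usd=None):
    n = len(intensities)
    crop_intensities = crop_intensities if crop_intensities is not None else [1.0] * n
    gen = np.asarray(generations, float)
    crop = (
        np.asarray(crop_usd, float)
        if crop_usd is not None
        else np.asarray(crop_intensities, float) * gen
    )
    mort_usd = np.asarray(intensities, float) * gen * VSL
    return pd.DataFrame(
        {
            "station_id": [f"s{i:02d}" for i in range(n)],
            "annual_generation_gwh": gen,
            "mortality_intensity": intensities,
            "crop_intensity_annual": crop_intensities,
            "crop_usd": crop,
            "crop_usd_lo": 0.9 * crop,
            "crop_usd_hi": 1.1 * crop,
            "mortality_usd": mort_usd,
            "mortality_usd_lo": 0.8 * mort_usd,
            "mortality_usd_hi": 1.2 * mort_usd,
        }
    )


class TestRankAndSelect:
    def test_three_station_example(self):
        # intensities (10, 5, 1)/GWh at 40 GWh each; budget 80 GWh -> top two
        ledger = make_ledger([10 / VSL, 5 / VSL, 1 / VSL], [40.0, 40.0, 40.0])
        scen = rank_and_select(ledger, "mortality", budget_fraction=80.0 / 120.0)
        assert list(scen.selected["station_id"]) == ["s00", "s01"]

    def test_full_budget_selects_all(self):
        ledger = make_ledger([0.03, 0.02, 0.01], [10.0, 20.0, 30.0])
        scen = rank_and_select(ledger, "mortality", budget_fraction=1.0)
        assert len(scen.selected) == 3

    def test_budget_below_top_station_empty(self):
        ledger = make_ledger([0.05, 0.01], [100.0, 100.0])
        scen = rank_and_select(ledger, "mortality", budget_fraction=0.10)
        assert scen.selected.empty
        assert scen.benefits["total_usd"] == 0.0

    def test_budget_never_violated(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(2, 10)
            ledger = make_ledger(
                rng.uniform(0.001, 0.1, n), rng.uniform(10, 500, n),
                crop_intensities=rng.uniform(100, 20000, n),
            )
            for obj in ("mortality", "crop", "combined"):
                scen = rank_and_select(ledger, obj, budget_fraction=0.10)
                assert scen.selected_generation_gwh <= scen.budget_gwh + 1e-9

    def test_greedy_prefix_matches_enumeration(self):
        """Among all rank-order prefixes fitting the budget, greedy picks the
        one with maximal summed damages (exhaustive check, <=12 stations)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            ledger = make_ledger(
                rng.uniform(0.001, 0.1, n), rng.uniform(10, 300, n)
            )
            budget_fraction = float(rng.uniform(0.1, 0.6))
            scen = rank_and_select(ledger, "mortality", budget_fraction)
            budget = budget_fraction * ledger["annual_generation_gwh"].sum()
            ranked = ledger.sort_values(
                ["mortality_intensity", "station_id"], ascending=[False, True]
            ).reset_index(drop=True)
            best, best_damage = [], -1.0
            for k in range(n + 1):
                prefix = ranked.iloc[:k]
                if prefix["annual_generation_gwh"].sum() > budget:
                    break
                damage = (
                    prefix["mortality_intensity"] * prefix["annual_generation_gwh"] * VSL
                ).sum()
                if damage > best_damage:
                    best, best_damage = list(prefix["station_id"]), damage
            assert list(scen.selected["station_id"]) == best

    def test_stations_without_mortality_excluded(self):
        ledger = make_ledger([0.05, 0.04], [50.0, 50.0])
        ledger.loc[1, "mortality_intensity"] = np.nan
        scen = rank_and_select(ledger, "combined", budget_fraction=1.0)
        assert list(scen.selected["station_id"]) == ["s00"]

    def test_bad_budget_rejected(self):
        ledger = make_ledger([0.05], [50.0])
        with pytest.raises(ValueError):
            rank_and_select(ledger, "mortality", budget_fraction=0.0)


class TestScenarioBenefits:
    def test_hand_arithmetic(self):
        # 0.035 deaths/GWh x 1000 GWh/y x US$120k -> US$4.2M/y mortality
        ledger = make_ledger([0.035], [1000.0], crop_usd=[0.0])
        scen = rank_and_select(ledger, "mortality", budget_fraction=1.0)
        assert scen.benefits["mortality_usd"] == pytest.approx(4_200_000.0)
        assert scen.benefits["total_usd"] == pytest.approx(4_200_000.0)

    def test_crop_counted_regardless_of_objective(self):
        ledger = make_ledger([0.05, 0.01], [50.0, 50.0], crop_usd=[1000.0, 90000.0])
        scen = rank_and_select(ledger, "mortality", budget_fraction=0.5)
        assert scen.benefits["crop_usd"] == 1000.0

    def test_objective_dominance_equal_sized_stations(self):
        """With equal-generation stations the crop objective never yields
        lower crop benefits than the mortality objective. (With unequal
        sizes the stop-before-exceed rule admits counterexamples: the crop
        ranking's top station can alone overflow the budget.)"""
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            ledger = make_ledger(
                rng.uniform(0.001, 0.1, n), np.full(n, 100.0),
                crop_intensities=rng.uniform(100, 20000, n),
            )
            bf = float(rng.uniform(0.1, 0.9))
            crop_obj = rank_and_select(ledger, "crop", bf)
            mort_obj = rank_and_select(ledger, "mortality", bf)
            assert crop_obj.benefits["crop_usd"] >= mort_obj.benefits["crop_usd"] - 1e-9


def make_seasonal(ledger, rng):
    rows = []
    for _, r in ledger.iterrows():
        for season in ("monsoon_2019", "winter_2019"):
            gen = r["annual_generation_gwh"] / 2
            ci = float(rng.uniform(0, 20000))
            rows.append(
                {
                    "station_id": r["station_id"], "season_id": season,
                    "crop": "rice" if "monsoon" in season else "wheat",
                    "seasonal_generation_gwh": gen, "crop_intensity": ci,
                    "crop_usd": ci * gen, "crop_usd_lo": 0.9 * ci * gen,
                    "crop_usd_hi": 1.1 * ci * gen,
                }
            )
    return pd.DataFrame(rows)


class TestSeasonalSelection:
    def test_units_are_station_seasons(self):
        rng = np.random.default_rng(3)
        ledger = make_ledger([0.05, 0.01], [100.0, 100.0])
        seasonal = make_seasonal(ledger, rng)
        scen = seasonal_selection(ledger, seasonal, budget_fraction=0.25)
        # budget 50 GWh = one 50-GWh seasonal unit
        assert len(scen.selected) == 1
        assert scen.selected_generation_gwh <= 0.25 * 200.0

    def test_zero_crop_reduces_to_mortality_ranking(self):
        rng = np.random.default_rng(4)
        ledger = make_ledger([0.08, 0.05, 0.01], [100.0, 100.0, 100.0])
        seasonal = make_seasonal(ledger, rng)
        seasonal[["crop_intensity", "crop_usd", "crop_usd_lo", "crop_usd_hi"]] = 0.0
        scen = seasonal_selection(ledger, seasonal, budget_fraction=0.5)
        picked = scen.selected["station_id"].tolist()
        # highest mortality stations' seasons first
        assert set(picked[:2]) == {"s00"}  # both seasons of the top station

    def test_greedy_matches_brute_force_prefix(self):
        rng = np.random.default_rng(5)
        ledger = make_ledger(rng.uniform(0.001, 0.1, 4), rng.uniform(50, 150, 4))
        seasonal = make_seasonal(ledger, rng)
        scen = seasonal_selection(ledger, seasonal, budget_fraction=0.4)
        budget = 0.4 * ledger["annual_generation_gwh"].sum()
        units = seasonal.merge(
            ledger[["station_id", "mortality_intensity"]], on="station_id"
        )
        units["rank_int"] = units["mortality_intensity"] * VSL + units["crop_intensity"]
        units = units.sort_values(
            ["rank_int", "station_id", "season_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        cum, take = 0.0, []
        for _, r in units.iterrows():
            if cum + r["seasonal_generation_gwh"] > budget:
                break
            take.append((r["station_id"], r["season_id"]))
            cum += r["seasonal_generation_gwh"]
        got = list(zip(scen.selected["station_id"], scen.selected["season_id"]))
        assert got == take


class TestBenefitRange:
    def test_degenerate_bounds_collapse(self):
        ledger = make_ledger([0.05, 0.02], [50.0, 50.0])
        for c in ("crop_usd_lo", "crop_usd_hi"):
            ledger[c] = ledger["crop_usd"]
        for c in ("mortality_usd_lo", "mortality_usd_hi"):
            ledger[c] = ledger["mortality_usd"]
        scen = rank_and_select(ledger, "mortality", budget_fraction=1.0)
        lo, hi = benefit_range(scen, ledger)
        assert lo == pytest.approx(hi)

    def test_range_widens_with_more_stations(self):
        ledger = make_ledger([0.05, 0.04, 0.03], [10.0, 10.0, 10.0])
        widths = []
        for bf in (0.34, 0.67, 1.0):
            scen = rank_and_select(ledger, "mortality", budget_fraction=bf)
            lo, hi = benefit_range(scen, ledger)
            widths.append(hi - lo)
        assert widths[0] <= widths[1] <= widths[2]

    def test_hand_sum(self):
        ledger = make_ledger([0.05], [100.0], crop_usd=[1000.0])
        scen = rank_and_select(ledger, "mortality", budget_fraction=1.0)
        lo, hi = benefit_range(scen, ledger)
        mort = 0.05 * 100.0 * VSL
        assert lo == pytest.approx(0.9 * 1000.0 + 0.8 * mort)
        assert hi == pytest.approx(1.1 * 1000.0 + 1.2 * mort)
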