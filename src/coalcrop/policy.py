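"""Rank-and-cut prioritization of stations for emissions reduction.

Stations (or station-season units) are ranked in descending order of a
damage intensity — monetized mortality per GWh, annual crop damages per
GWh, or their sum — and selected greedily until their cumulative
generation would exceed a budget expressed as a fraction (default 10%) of
total annual generation. Selection stops at the first unit that would
cross the budget; there is no fractional selection and no skipping ahead
to smaller stations. Only stations with both mortality and crop intensity
estimates participate.

The benefit range attached to a scenario sums per-station crop percentile
bounds and mortality bounds; it is a *range*, not a prediction interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OBJECTIVES = ("mortality", "crop", "combined", "combined_seasonal")

#: columns a station ledger must provide
LEDGER_COLUMNS = (
    "station_id",
    "annual_generation_gwh",
    "mortality_intensity",  # deaths/GWh
    "crop_intensity_annual",  # USD/GWh
    "crop_usd",  # annual crop damages, USD/y (point estimate)
    "crop_usd_lo",
    "crop_usd_hi",
    "mortality_usd",  # annual mortality damages, USD/y (point estimate)
    "mortality_usd_lo",
    "mortality_usd_hi",
)


@dataclass
class PolicyScenario:
    objective: str
    budget_fraction: float
    budget_gwh: float
    selected: pd.DataFrame  # ordered units with per-unit benefits
    benefits: dict = field(default_factory=dict)
    benefit_bounds: tuple = (np.nan, np.nan)

    @property
    def selected_generation_gwh(self) -> float:
        return float(self.selected["unit_generation_gwh"].sum())

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "budget_fraction": self.budget_fraction,
            "budget_gwh": self.budget_gwh,
            "selected_generation_gwh": self.selected_generation_gwh,
            "selected": self.selected.to_dict("records"),
            "benefits": self.benefits,
            "benefit_range": {"lo": self.benefit_bounds[0], "hi": self.benefit_bounds[1]},
        }


def _greedy_prefix(units: pd.DataFrame, budget_gwh: float) -> pd.DataFrame:
    """Take the ranked prefix whose cumulative generation stays <= budget,
    stopping at the first unit that would exceed it."""
    take = []
    cum = 0.0
    for _, row in units.iterrows():
        if cum + row["unit_generation_gwh"] > budget_gwh:
            break
        take.append(row)
        cum += row["unit_generation_gwh"]
    return pd.DataFrame(take, columns=units.columns).reset_index(drop=True)


def rank_and_select(
    ledger: pd.DataFrame,
    objective: str,
    budget_fraction: float = 0.10,
    vsl: float = 120000.0,
) -> PolicyScenario:
    """Greedy annual-unit selection under a generation budget.

    Ranking intensity: mortality = deaths/GWh x VSL; crop = annual crop
    USD/GWh; combined = their sum. Ties break by station_id ascending. The
    budget is ``budget_fraction`` of the summed annual generation of every
    station in the ledger.
    """
    if budget_fraction <= 0:
        raise ValueError("budget_fraction must be positive")
    if objective not in ("mortality", "crop", "combined"):
        raise ValueError(f"objective must be one of mortality/crop/combined, got {objective!r}")
    total_gen = float(ledger["annual_generation_gwh"].sum())
    budget = budget_fraction * total_gen

    eligible = ledger.dropna(
        subset=["mortality_intensity", "crop_intensity_annual"]
    ).copy()
    eligible["mortality_usd_per_gwh"] = eligible["mortality_intensity"] * vsl
    intensity = {
        "mortality": eligible["mortality_usd_per_gwh"],
        "crop": eligible["crop_intensity_annual"],
        "combined": eligible["mortality_usd_per_gwh"] + eligible["crop_intensity_annual"],
    }[objective]
    eligible["ranking_intensity"] = intensity
    eligible["unit_generation_gwh"] = eligible["annual_generation_gwh"]
    eligible = eligible.sort_values(
        ["ranking_intensity", "station_id"], ascending=[False, True]
    ).reset_index(drop=True)

    selected = _greedy_prefix(eligible, budget)
    scenario = PolicyScenario(
        objective=objective,
        budget_fraction=budget_fraction,
        budget_gwh=budget,
        selected=selected,
    )
    scenario.benefits = scenario_benefits(scenario, ledger, vsl=vsl)
    scenario.benefit_bounds = benefit_range(scenario, ledger)
    return scenario


def scenario_benefits(scenario: PolicyScenario, ledger: pd.DataFrame, vsl: float = 120000.0) -> dict:
    """Monetized annual benefits of a selection.

    Mortality: sum over selected units of deaths/GWh x unit GWh x VSL.
    Crop: the selected units' annual (or seasonal) crop damages, counted
    for every selected station regardless of the ranking objective.
    """
    sel = scenario.selected
    if sel.empty:
        return {"mortality_usd": 0.0, "crop_usd": 0.0, "total_usd": 0.0}
    mort = float((sel["mortality_intensity"] * sel["unit_generation_gwh"] * vsl).sum())
    crop_col = "unit_crop_usd" if "unit_crop_usd" in sel.columns else "crop_usd"
    crop = float(sel[crop_col].sum())
    return {"mortality_usd": mort, "crop_usd": crop, "total_usd": mort + crop}


def seasonal_selection(
    ledger: pd.DataFrame,
    seasonal: pd.DataFrame,
    budget_fraction: float = 0.10,
    vsl: float = 120000.0,
) -> PolicyScenario:
    """Greedy selection over station x season units.

    ``seasonal`` columns: station_id, season_id, seasonal_generation_gwh,
    crop_intensity (USD/GWh), crop_usd, crop_usd_lo, crop_usd_hi. The
    mortality intensity is assumed uniform across the year, so a seasonal
    unit's ranking intensity is the station's monetized mortality intensity
    plus that season's crop intensity. The budget is still measured against
    total ANNUAL generation.
    """
    if budget_fraction <= 0:
        raise ValueError("budget_fraction must be positive")
    total_gen = float(ledger["annual_generation_gwh"].sum())
    budget = budget_fraction * total_gen

    units = seasonal.merge(
        ledger[["station_id", "mortality_intensity", "crop_intensity_annual",
                "mortality_usd_lo", "mortality_usd_hi", "annual_generation_gwh"]],
        on="station_id",
        how="inner",
    ).dropna(subset=["mortality_intensity", "crop_intensity"]).copy()
    units["mortality_usd_per_gwh"] = units["mortality_intensity"] * vsl
    units["ranking_intensity"] = units["mortality_usd_per_gwh"] + units["crop_intensity"]
    units["unit_generation_gwh"] = units["seasonal_generation_gwh"]
    units["unit_crop_usd"] = units["crop_usd"]
    units = units.sort_values(
        ["ranking_intensity", "station_id", "season_id"], ascending=[False, True, True]
    ).reset_index(drop=True)

    selected = _greedy_prefix(units, budget)
    scenario = PolicyScenario(
        objective="combined_seasonal",
        budget_fraction=budget_fraction,
        budget_gwh=budget,
        selected=selected,
    )
    scenario.benefits = scenario_benefits(scenario, ledger, vsl=vsl)
    # seasonal range: per-unit seasonal crop bounds + mortality bounds scaled
    # to the unit's share of annual generation
    if selected.empty:
        scenario.benefit_bounds = (0.0, 0.0)
    else:
        share = selected["unit_generation_gwh"] / selected["annual_generation_gwh"]
        lo = float((selected["crop_usd_lo"]).sum() + (selected["mortality_usd_lo"] * share).sum())
        hi = float((selected["crop_usd_hi"]).sum() + (selected["mortality_usd_hi"] * share).sum())
        scenario.benefit_bounds = (lo, hi)
    return scenario


def benefit_range(scenario: PolicyScenario, ledger: pd.DataFrame) -> tuple:
    """(lo, hi) total-benefit range for an annual-unit scenario.

    lo = sum of selected stations' 2.5th-percentile crop damages plus lower
    mortality estimates; hi analogously with 97.5th percentiles and upper
    mortality estimates. Not a prediction interval.
    """
    sel = scenario.selected
    if sel.empty:
        return (0.0, 0.0)
    lo = float(sel["crop_usd_lo"].sum() + sel["mortality_usd_lo"].sum())
    hi = float(sel["crop_usd_hi"].sum() + sel["mortality_usd_hi"].sum())
    return (lo, hi)
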