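"""County x age counterfactual impacts of climate and CO2 change.

For a stand of a given age and location, the factual volume in the
evaluation year is compared with the volume of a *comparable* stand
(same location, group, age, origin) whose lifetime-exposure windows end
in the base year.  A driver subset selects which of temperature,
precipitation and CO2 are moved to the evaluation year; the rest stay at
the base year.  Because the yield model is log-linear, impact factors
multiply exactly across disjoint driver subsets, and a CO2-only impact
has the closed form ``(Cbar_eval / Cbar_base)^gamma - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import SEASONS, CO2Index, ClimateIndex, ExposureCovariates
from .yield_model import YieldResults

CLIMATE_DRIVERS = ("temperature", "precipitation", "co2")


@dataclass(frozen=True)
class ImpactCell:
    """Impact of a driver subset on one (location, age) stand."""

    location: str
    age: int
    group: str
    drivers: frozenset
    base_volume: float       # m^3/ha, all drivers at base year
    scenario_volume: float   # m^3/ha, subset drivers at evaluation year
    impact_abs: float        # m^3/ha
    impact_pct: float        # 100 * (V_scen - V_base) / V_base


def scenario_exposure(
    location: str,
    age: int,
    eval_year: int,
    held: Iterable[str],
    base_year: int,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
) -> ExposureCovariates:
    """Exposure with the ``held`` drivers' windows ending in the base year.

    Drivers not in ``held`` use windows ending in the evaluation year.
    All windows have length ``age``.
    """
    held = set(held)
    unknown = held - set(CLIMATE_DRIVERS)
    if unknown:
        raise ValueError(f"unknown drivers {sorted(unknown)}")
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)

    def window(driver):
        y = base_year if driver in held else eval_year
        return y - age + 1, y

    wt, wp, wc = window("temperature"), window("precipitation"), window("co2")
    return ExposureCovariates(
        location=location, age=age, year=eval_year,
        tmean={s: cidx.window_mean(location, s, "tmean", *wt) for s in SEASONS},
        prcp={s: cidx.window_mean(location, s, "prcp", *wp) for s in SEASONS},
        co2=xidx.window_mean(*wc),
    )


def driver_impact(
    results: YieldResults,
    location: str,
    age: int,
    drivers: Iterable[str],
    base_year: int,
    eval_year: int,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
    group: str,
) -> ImpactCell:
    """Volume impact of moving ``drivers`` from base-year to eval-year exposure.

    The base stand has every driver's window ending in ``base_year``;
    the scenario moves only the listed drivers to ``eval_year``.
    """
    drivers = frozenset(drivers)
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    base_expo = scenario_exposure(location, age, eval_year, CLIMATE_DRIVERS,
                                  base_year, cidx, xidx)
    scen_expo = scenario_exposure(location, age, eval_year,
                                  set(CLIMATE_DRIVERS) - drivers,
                                  base_year, cidx, xidx)
    v0 = results.predict_volume(base_expo, age=age, group=group)
    v1 = results.predict_volume(scen_expo, age=age, group=group)
    return ImpactCell(
        location=location, age=age, group=group, drivers=drivers,
        base_volume=v0, scenario_volume=v1,
        impact_abs=v1 - v0, impact_pct=100.0 * (v1 - v0) / v0,
    )


def impact_table(
    results: YieldResults,
    group: str,
    locations: Sequence[str],
    ages: Sequence[int],
    driver_subsets: Sequence[Iterable[str]],
    base_year: int,
    eval_year: int,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
) -> pd.DataFrame:
    """Tidy table of impacts over locations x ages x driver subsets."""
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    rows = []
    for subset in driver_subsets:
        label = "+".join(sorted(subset))
        for loc in locations:
            for age in ages:
                cell = driver_impact(results, loc, age, subset, base_year,
                                     eval_year, cidx, xidx, group)
                rows.append({
                    "location": loc, "age": age, "group": group,
                    "drivers": label, "base_volume_m3ha": cell.base_volume,
                    "impact_m3ha": cell.impact_abs, "impact_pct": cell.impact_pct,
                })
    return pd.DataFrame(rows)


def impact_summary(
    cells: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-age (optionally area-weighted) mean impact across locations.

    ``cells`` is the tidy output of :func:`impact_table`.  ``weights``
    maps location -> non-negative weight (default: unweighted means, the
    county-map convention); must cover every location and not be all
    zero.
    """
    if weights is not None:
        missing = set(cells["location"].unique()) - set(weights)
        if missing:
            raise ValueError(f"weights missing for locations {sorted(missing)}")
        w = cells["location"].map(weights).astype(float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if w.sum() == 0:
            raise ValueError("weights must not all be zero")
    else:
        w = pd.Series(1.0, index=cells.index)
    out = []
    for (drivers, age), grp in cells.groupby(["drivers", "age"]):
        ww = w.loc[grp.index].to_numpy()
        out.append({
            "drivers": drivers, "age": age,
            "mean_impact_m3ha": float(np.average(grp["impact_m3ha"], weights=ww)),
            "mean_impact_pct": float(np.average(grp["impact_pct"], weights=ww)),
        })
    return pd.DataFrame(out)
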