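"""Six-driver decomposition of regional wood-volume change.

A region's stock implied by the yield model is a function of six driver
"coordinates" that can each be set to their start-census or end-census
state independently:

- **area**: per-group total forest area (ha);
- **age**: the per-group distribution of area over age classes and origins;
- **temperature / precipitation / CO2**: the calendar year in which every
  stand's lifetime-exposure window ends;
- **planting**: the planted-minus-natural volume premium pool, evaluated
  on a census's own planted areas (decoupled from the area/age
  coordinates, so the whole planted-stand gain is attributed to the
  planting driver, netting the start-census gap from the end-census gap).

The decomposition telescopes: drivers are swapped from start to end state
one at a time in a fixed order, each contribution being the stock
difference the swap produces.  Contributions therefore sum *exactly* to
the model-explained change; the gap to the observed (censused) change is
the unexplained residual (disturbance, pests, fire, N deposition, ...).
Order dependence is quantified, not hidden: `reorder_sensitivity`
recomputes contributions under driver-order permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import SEASONS, CO2Index, ClimateIndex, ExposureCovariates
from .yield_model import YieldResults

DRIVERS = ("area", "age", "temperature", "precipitation", "co2", "planting")

AREA_COLUMNS = ("group", "age_lo", "age_hi", "origin", "area_ha")

# callable (group, age) -> planted-minus-natural volume premium in m^3/ha
PremiumFn = Callable[[str, float], float]


def midpoint_age(age_lo: int, age_hi: int) -> int:
    """Integer midpoint of an inclusive age class, rounding half up."""
    return (int(age_lo) + int(age_hi) + 1) // 2


@dataclass
class InventoryTable:
    """Census of forest area and observed volume at one year in one region.

    ``areas`` has columns ``group, age_lo, age_hi, origin, area_ha`` (ha);
    ``observed_volume`` has columns ``group, volume_m3`` with the total
    volume the census itself recorded for each group.
    """

    region: str
    year: int
    areas: pd.DataFrame
    observed_volume: pd.DataFrame

    def __post_init__(self):
        missing = set(AREA_COLUMNS) - set(self.areas.columns)
        if missing:
            raise ValueError(f"areas table missing columns {sorted(missing)}")
        if (self.areas["area_ha"] < 0).any():
            raise ValueError("negative area in inventory")
        for (g, o), grp in self.areas.groupby(["group", "origin"]):
            intervals = sorted(zip(grp["age_lo"], grp["age_hi"]))
            for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"overlapping age classes for group={g!r}, origin={o!r}: "
                        f"[{lo1},{hi1}] and [{lo2},{hi2}]"
                    )

    @property
    def total_observed_volume(self) -> float:
        return float(self.observed_volume["volume_m3"].sum())

    @property
    def total_area(self) -> float:
        return float(self.areas["area_ha"].sum())


@dataclass
class AttributionResult:
    """Driver contributions to one region's volume change over one period.

    Contributions and totals are in million m^3 of aboveground volume.
    ``explained`` is the exact sum of the six contributions (telescoping);
    ``unexplained = observed_change - explained``.
    """

    region: str
    period: tuple[int, int]
    contributions: dict[str, float]
    explained: float
    observed_change: float
    unexplained: float
    order: tuple[str, ...] = DRIVERS

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": self.region, "period_start": self.period[0],
             "period_end": self.period[1], "driver": d,
             "volume_million_m3": self.contributions[d]}
            for d in self.order
        ]
        for label, val in (
            ("explained", self.explained),
            ("observed", self.observed_change),
            ("unexplained", self.unexplained),
        ):
            rows.append({"region": self.region, "period_start": self.period[0],
                         "period_end": self.period[1], "driver": label,
                         "volume_million_m3": val})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Volume change attribution — {self.region}, "
                 f"{self.period[0]}–{self.period[1]} (million m^3)"]
        for d in self.order:
            lines.append(f"  {d:<14}{self.contributions[d]:>10.1f}")
        lines.append(f"  {'explained':<14}{self.explained:>10.1f}")
        lines.append(f"  {'observed':<14}{self.observed_change:>10.1f}")
        lines.append(f"  {'unexplained':<14}{self.unexplained:>10.1f}")
        return "\n".join(lines)


def mixed_exposure(
    location: str,
    age: int,
    climate: ClimateIndex,
    co2: CO2Index,
    temp_year: int,
    precip_year: int,
    co2_year: int,
) -> ExposureCovariates:
    """Lifetime exposure whose T, P and CO2 windows may end in different years.

    Each window has length ``age`` and ends in the driver's own state
    year; used to evaluate counterfactual driver states.
    """
    wt = (temp_year - age + 1, temp_year)
    wp = (precip_year - age + 1, precip_year)
    wc = (co2_year - age + 1, co2_year)
    return ExposureCovariates(
        location=location, age=age, year=max(temp_year, precip_year, co2_year),
        tmean={s: climate.window_mean(location, s, "tmean", *wt) for s in SEASONS},
        prcp={s: climate.window_mean(location, s, "prcp", *wp) for s in SEASONS},
        co2=co2.window_mean(*wc),
    )


def _base_stock(
    results: YieldResults,
    areas: pd.DataFrame,
    climate: ClimateIndex,
    co2: CO2Index,
    location: str,
    temp_year: int,
    precip_year: int,
    co2_year: int,
) -> float:
    """Sum of area x predicted natural-yield volume over all census cells (m^3)."""
    total = 0.0
    cache: dict[int, ExposureCovariates] = {}
    for row in areas.itertuples(index=False):
        if row.area_ha == 0:
            continue
        age = midpoint_age(row.age_lo, row.age_hi)
        if age not in cache:
            cache[age] = mixed_exposure(
                location, age, climate, co2, temp_year, precip_year, co2_year
            )
        total += row.area_ha * results.predict_volume(cache[age], age=age, group=row.group)
    return total


def premium_pool(areas: pd.DataFrame, premium: PremiumFn) -> float:
    """Total planted-minus-natural volume gap over a census's planted cells (m^3)."""
    total = 0.0
    planted = areas[areas["origin"] == "planted"]
    for row in planted.itertuples(index=False):
        total += row.area_ha * premium(row.group, midpoint_age(row.age_lo, row.age_hi))
    return total


def aggregate_volume(
    results: YieldResults,
    areas: pd.DataFrame,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
    *,
    location: str,
    temp_year: int,
    precip_year: int,
    co2_year: int,
    planting: bool = False,
    premium: PremiumFn | None = None,
) -> float:
    """Total stock (m^3) implied by a driver state vector.

    Sums ``area x predict_volume`` at each age-class midpoint; when
    ``planting`` is on, the planted-stand premium is added for the table's
    own planted cells.
    """
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    total = _base_stock(results, areas, cidx, xidx, location, temp_year, precip_year, co2_year)
    if planting:
        if premium is None:
            raise ValueError("planting=True requires a premium schedule")
        total += premium_pool(areas, premium)
    return total


# -- telescoping decomposition ---------------------------------------------


def _group_totals_and_shares(areas: pd.DataFrame, grid: pd.DataFrame):
    """Per-group total area and per-cell shares on a common cell grid."""
    merged = grid.merge(areas, on=["group", "age_lo", "age_hi", "origin"], how="left")
    a = merged["area_ha"].fillna(0.0).to_numpy()
    totals = pd.Series(a, index=merged["group"]).groupby(level=0).sum()
    denom = totals.reindex(merged["group"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(denom > 0, a / denom, 0.0)
    return totals, shares


class _Decomposer:
    """Evaluates the region stock at any of the 2^6 driver-state corners."""

    def __init__(
        self,
        results: YieldResults,
        inv_start: InventoryTable,
        inv_end: InventoryTable,
        climate: ClimateIndex,
        co2: CO2Index,
        premium: PremiumFn,
        location: str,
    ):
        if inv_start.region != inv_end.region:
            raise ValueError("inventories are for different regions")
        g1 = set(inv_start.areas["group"])
        g2 = set(inv_end.areas["group"])
        if g1 != g2:
            raise ValueError(f"census group structure differs: {sorted(g1 ^ g2)}")
        self.results = results
        self.climate = climate
        self.co2 = co2
        self.premium = premium
        self.location = location
        self.years = {"start": inv_start.year, "end": inv_end.year}
        self.inv = {"start": inv_start, "end": inv_end}
        grid = pd.concat(
            [inv_start.areas[list(AREA_COLUMNS[:4])], inv_end.areas[list(AREA_COLUMNS[:4])]]
        ).drop_duplicates().sort_values(list(AREA_COLUMNS[:4])).reset_index(drop=True)
        self.grid = grid
        self.totals = {}
        self.shares = {}
        for state in ("start", "end"):
            t, s = _group_totals_and_shares(self.inv[state].areas, grid)
            self.totals[state] = t
            self.shares[state] = s
        # a group can be absent (zero area) in one census: its age shares are
        # then taken from the census where it exists, attributing the whole
        # change to the area driver
        for state, other in (("start", "end"), ("end", "start")):
            zero = self.totals[state][self.totals[state] == 0].index
            if len(zero):
                mask = self.grid["group"].isin(zero).to_numpy()
                self.shares[state] = np.where(
                    mask, self.shares[other], self.shares[state]
                )
        self._premium_pool = {
            s: premium_pool(self.inv[s].areas, premium) for s in ("start", "end")
        }
        self._stock_cache: dict[tuple, float] = {}

    def areas_for(self, area_state: str, age_state: str) -> pd.DataFrame:
        out = self.grid.copy()
        totals = self.totals[area_state].reindex(out["group"]).to_numpy()
        out["area_ha"] = totals * self.shares[age_state]
        return out

    def stock(self, state: Mapping[str, str]) -> float:
        """Stock (m^3) at a corner; ``state`` maps driver -> 'start'|'end'."""
        key = tuple(state[d] for d in DRIVERS)
        if key not in self._stock_cache:
            areas = self.areas_for(state["area"], state["age"])
            base = _base_stock(
                self.results, areas, self.climate, self.co2, self.location,
                temp_year=self.years[state["temperature"]],
                precip_year=self.years[state["precipitation"]],
                co2_year=self.years[state["co2"]],
            )
            self._stock_cache[key] = base + self._premium_pool[state["planting"]]
        return self._stock_cache[key]

    def contributions(self, order: Sequence[str]) -> dict[str, float]:
        if sorted(order) != sorted(DRIVERS):
            raise ValueError(f"order must be a permutation of {DRIVERS}")
        state = {d: "start" for d in DRIVERS}
        prev = self.stock(state)
        out = {}
        for d in order:
            state[d] = "end"
            cur = self.stock(state)
            out[d] = cur - prev
            prev = cur
        return out


def decompose(
    results: YieldResults,
    inv_start: InventoryTable,
    inv_end: InventoryTable,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
    premium: PremiumFn,
    *,
    location: str,
    order: Sequence[str] = DRIVERS,
) -> AttributionResult:
    """Telescoping six-driver attribution of one region's volume change.

    Swaps drivers from their start-census to end-census states in
    ``order``; contributions sum exactly to the explained change and the
    residual to the observed census change is reported as unexplained.
    Results are in million m^3.
    """
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    dec = _Decomposer(results, inv_start, inv_end, cidx, xidx, premium, location)
    contrib = dec.contributions(order)
    explained = sum(contrib.values())
    observed = inv_end.total_observed_volume - inv_start.total_observed_volume
    M = 1e6
    return AttributionResult(
        region=inv_start.region,
        period=(inv_start.year, inv_end.year),
        contributions={d: c / M for d, c in contrib.items()},
        explained=explained / M,
        observed_change=observed / M,
        unexplained=(observed - explained) / M,
        order=tuple(order),
    )


def reorder_sensitivity(
    results: YieldResults,
    inv_start: InventoryTable,
    inv_end: InventoryTable,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
    premium: PremiumFn,
    *,
    location: str,
    permutations: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Range of each driver's contribution across substitution orders.

    Runs the telescoping decomposition under every permutation given
    (default: all 720) and returns per-driver min/max/default
    contributions in million m^3 plus the (order-invariant) explained
    total.
    """
    if permutations is None:
        permutations = list(itertools.permutations(DRIVERS))
    if len(permutations) > 720:
        raise ValueError("at most 720 permutations")
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    dec = _Decomposer(results, inv_start, inv_end, cidx, xidx, premium, location)
    rows = {d: [] for d in DRIVERS}
    explained = []
    for perm in permutations:
        contrib = dec.contributions(perm)
        for d in DRIVERS:
            rows[d].append(contrib[d])
        explained.append(sum(contrib.values()))
    default = dec.contributions(DRIVERS)
    M = 1e6
    out = pd.DataFrame({
        "driver": list(DRIVERS),
        "min_million_m3": [min(rows[d]) / M for d in DRIVERS],
        "max_million_m3": [max(rows[d]) / M for d in DRIVERS],
        "default_million_m3": [default[d] / M for d in DRIVERS],
    })
    out.attrs["explained_million_m3"] = explained[0] / M
    out.attrs["explained_range_m3"] = max(explained) - min(explained)
    return out
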