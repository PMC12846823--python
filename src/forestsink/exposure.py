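"""Lifetime environmental exposure of forest stands.

A stand of age *a* measured in calendar year *y* has lived through the
inclusive window ``[y - a + 1, y]`` of length exactly *a* years.  Its
*lifetime exposure* to a seasonal climate variable (or to atmospheric CO2)
is the arithmetic mean of that variable over the window.  Two stands of
the same age measured in different years share part of their lifetime
window when the windows overlap: a 100-year-old stand in 2023 and a
100-year-old stand in 1960 share the 37 calendar years 1924-1960, while
25-year-old stands measured in those years have disjoint windows separated
by a 39-year gap.

Exposure covariates are the regressors of the yield model: four seasonal
lifetime-mean temperatures, four seasonal lifetime-mean precipitation
totals, and the lifetime-mean CO2 concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SEASONS = ("winter", "spring", "summer", "fall")

CLIMATE_COLUMNS = ("location", "season", "year", "tmean_c", "prcp_mm")
CO2_COLUMNS = ("year", "co2_ppm")


def exposure_window(age: int, year: int) -> tuple[int, int]:
    """Inclusive calendar-year window lived by a stand of ``age`` in ``year``."""
    if age < 1:
        raise ValueError(f"age must be >= 1, got {age}")
    return year - age + 1, year


def window_overlap(age1: int, year1: int, age2: int, year2: int) -> int:
    """Number of calendar years shared by the two lifetime windows (>= 0)."""
    s1, e1 = exposure_window(age1, year1)
    s2, e2 = exposure_window(age2, year2)
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def window_gap(age1: int, year1: int, age2: int, year2: int) -> int:
    """Gap between the two windows: later window's start minus earlier window's end.

    Positive when the windows are disjoint (e.g. 39 years between the
    windows of 25-year-old stands measured in 1960 and 2023); zero or
    negative when they touch or overlap.
    """
    s1, e1 = exposure_window(age1, year1)
    s2, e2 = exposure_window(age2, year2)
    if s1 <= s2:
        (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
    return s1 - e2


@dataclass(frozen=True)
class ExposureCovariates:
    """Lifetime-mean climate and CO2 for one (location, age, year) stand."""

    location: str
    age: int
    year: int
    tmean: Mapping[str, float] = field(repr=False)   # season -> deg C
    prcp: Mapping[str, float] = field(repr=False)    # season -> mm
    co2: float = float("nan")                        # ppm

    @property
    def window(self) -> tuple[int, int]:
        return exposure_window(self.age, self.year)


class _SeriesIndex:
    """Cumulative-sum index over a contiguous annual series for O(1) window means."""

    def __init__(self, years: np.ndarray, values: np.ndarray, label: str):
        order = np.argsort(years)
        years = np.asarray(years)[order]
        values = np.asarray(values, dtype=float)[order]
        if len(years) == 0:
            raise ValueError(f"{label}: empty series")
        if np.any(np.diff(years) != 1):
            missing = sorted(set(range(years[0], years[-1] + 1)) - set(years.tolist()))
            raise ValueError(f"{label}: years not contiguous; missing {missing[:10]}")
        self.year0 = int(years[0])
        self.year1 = int(years[-1])
        self.label = label
        self._cum = np.concatenate([[0.0], np.cumsum(values)])

    def window_mean(self, start: int, end: int) -> float:
        return float(self.window_mean_vec(np.array([start]), np.array([end]))[0])

    def window_mean_vec(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        start = np.asarray(start)
        end = np.asarray(end)
        if start.min() < self.year0 or end.max() > self.year1:
            bad_lo = int(start.min())
            bad_hi = int(end.max())
            raise ValueError(
                f"{self.label}: window [{bad_lo}, {bad_hi}] not covered by "
                f"available years [{self.year0}, {self.year1}]"
            )
        i0 = start - self.year0
        i1 = end - self.year0 + 1
        return (self._cum[i1] - self._cum[i0]) / (end - start + 1)


class ClimateIndex:
    """Window-mean lookups into a (location, season, year) climate table."""

    def __init__(self, climate: pd.DataFrame):
        missing = set(CLIMATE_COLUMNS) - set(climate.columns)
        if missing:
            raise ValueError(f"climate table missing columns {sorted(missing)}")
        dup = climate.duplicated(subset=["location", "season", "year"])
        if dup.any():
            raise ValueError("climate table has duplicate (location, season, year) rows")
        if (climate["prcp_mm"] < 0).any():
            raise ValueError("negative precipitation in climate table")
        self._series: dict[tuple[str, str, str], _SeriesIndex] = {}
        for (loc, season), grp in climate.groupby(["location", "season"], sort=False):
            yrs = grp["year"].to_numpy()
            for var, col in (("tmean", "tmean_c"), ("prcp", "prcp_mm")):
                self._series[(loc, season, var)] = _SeriesIndex(
                    yrs, grp[col].to_numpy(), f"climate[{loc},{season},{var}]"
                )
        self.locations = tuple(climate["location"].unique())

    def series(self, location: str, season: str, var: str) -> _SeriesIndex:
        try:
            return self._series[(location, season, var)]
        except KeyError:
            raise KeyError(
                f"no climate series for location={location!r}, season={season!r}, var={var!r}"
            ) from None

    def window_mean(self, location: str, season: str, var: str, start: int, end: int) -> float:
        return self.series(location, season, var).window_mean(start, end)


class CO2Index:
    """Window-mean lookups into an annual CO2 concentration series."""

    def __init__(self, co2: pd.DataFrame):
        missing = set(CO2_COLUMNS) - set(co2.columns)
        if missing:
            raise ValueError(f"co2 table missing columns {sorted(missing)}")
        if (co2["co2_ppm"] <= 0).any():
            raise ValueError("non-positive CO2 concentration")
        self._series = _SeriesIndex(co2["year"].to_numpy(), co2["co2_ppm"].to_numpy(), "co2")

    def window_mean(self, start: int, end: int) -> float:
        return self._series.window_mean(start, end)

    def window_mean_vec(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        return self._series.window_mean_vec(start, end)


def lifetime_exposure(
    location: str,
    age: int,
    year: int,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
) -> ExposureCovariates:
    """Lifetime-mean seasonal climate and CO2 for one stand.

    Means are arithmetic averages over the inclusive window
    ``[year - age + 1, year]``; an error names the missing years when the
    climate or CO2 tables do not cover the window.
    """
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    start, end = exposure_window(age, year)
    tmean = {s: cidx.window_mean(location, s, "tmean", start, end) for s in SEASONS}
    prcp = {s: cidx.window_mean(location, s, "prcp", start, end) for s in SEASONS}
    return ExposureCovariates(
        location=location, age=age, year=year,
        tmean=tmean, prcp=prcp, co2=xidx.window_mean(start, end),
    )


def exposure_table(
    plots: pd.DataFrame,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
) -> pd.DataFrame:
    """Vectorised lifetime exposures for a table of plots.

    ``plots`` needs columns ``location``, ``age``, ``year``.  Returns a
    DataFrame aligned on the index of ``plots`` with columns
    ``T_<season>``, ``P_<season>`` and ``co2_mean``.
    """
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    age = plots["age"].to_numpy(dtype=int)
    year = plots["year"].to_numpy(dtype=int)
    start = year - age + 1
    cols = {f"{v}_{s}": np.full(len(plots), np.nan) for s in SEASONS for v in ("T", "P")}
    for loc, grp_idx in plots.groupby("location", sort=False).indices.items():
        s_loc = start[grp_idx]
        e_loc = year[grp_idx]
        for s in SEASONS:
            cols[f"T_{s}"][grp_idx] = cidx.series(loc, s, "tmean").window_mean_vec(s_loc, e_loc)
            cols[f"P_{s}"][grp_idx] = cidx.series(loc, s, "prcp").window_mean_vec(s_loc, e_loc)
    cols["co2_mean"] = xidx.window_mean_vec(start, year)
    return pd.DataFrame(cols, index=plots.index)
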