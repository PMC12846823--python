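"""Volume-to-carbon conversion, annualization, and passive/anthropogenic shares.

Aboveground wood-volume changes (million m^3) are converted to live-biomass
carbon (Tg C, including coarse roots) with region-specific scalar factors
pinned to the reference regional totals of the national assessment this
package operationalizes: South 1771/2232, North 786/1025 and West 27/54
Tg C per million m^3.  Passive drivers are temperature, precipitation and
CO2 fertilization; anthropogenic drivers are area change, age composition
and planting (management).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

PASSIVE_DRIVERS = ("temperature", "precipitation", "co2")
ANTHROPOGENIC_DRIVERS = ("area", "age", "planting")
ALL_DRIVERS = ANTHROPOGENIC_DRIVERS[:2] + PASSIVE_DRIVERS + ANTHROPOGENIC_DRIVERS[2:]

#: Tg C per million m^3 of aboveground volume, pinned to reference totals
DEFAULT_CARBON_FACTORS: dict[str, float] = {
    "South": 1771.0 / 2232.0,
    "North": 786.0 / 1025.0,
    "West": 27.0 / 54.0,
}


def volume_to_carbon(
    volume_million_m3: float,
    region: str,
    factors: Mapping[str, float] | None = None,
    rounded: bool = False,
) -> float:
    """Live-biomass carbon (Tg C, incl. coarse roots) of a volume change.

    ``rounded=True`` returns the integer-Tg reporting value; the default
    keeps full precision for further arithmetic.
    """
    factors = DEFAULT_CARBON_FACTORS if factors is None else factors
    if region not in factors:
        raise KeyError(f"no carbon factor for region {region!r}; have {sorted(factors)}")
    f = factors[region]
    if f <= 0:
        raise ValueError(f"carbon factor for {region!r} must be > 0")
    tg = volume_million_m3 * f
    return float(round(tg)) if rounded else float(tg)


def annualize(total: float, period_years: float) -> float:
    """Per-year rate of a period total."""
    if period_years <= 0:
        raise ValueError("period length must be > 0 years")
    return total / period_years


@dataclass(frozen=True)
class ShareReport:
    """Passive/anthropogenic split of a multi-region attribution."""

    total_million_m3: float
    passive_million_m3: float
    anthropogenic_million_m3: float
    passive_pct: float
    anthropogenic_pct: float
    planting_total_million_m3: float
    planting_regional_share_pct: dict[str, float]
    region_totals_million_m3: dict[str, float]

    def summary(self) -> str:
        lines = [
            f"Total six-driver change: {self.total_million_m3:,.0f} million m^3",
            f"  passive (T+P+CO2):     {self.passive_million_m3:,.0f} million m^3 "
            f"({self.passive_pct:.0f}%)",
            f"  anthropogenic:         {self.anthropogenic_million_m3:,.0f} million m^3 "
            f"({self.anthropogenic_pct:.0f}%)",
        ]
        for r, s in self.planting_regional_share_pct.items():
            lines.append(f"  planting share in {r}: {s:.1f}%")
        return "\n".join(lines)


def share_report(contributions: pd.DataFrame) -> ShareReport:
    """Passive and anthropogenic shares of the six-driver total.

    ``contributions`` is tidy with columns ``region``, ``driver``,
    ``volume_million_m3`` and must contain all six drivers (any region
    split).  Passive = temperature + precipitation + CO2.  Also reports
    each region's share of the total planting gain.
    """
    need = {"region", "driver", "volume_million_m3"}
    if not need <= set(contributions.columns):
        raise ValueError(f"contributions table needs columns {sorted(need)}")
    present = set(contributions["driver"])
    missing = set(ALL_DRIVERS) - present
    if missing:
        raise ValueError(f"missing drivers {sorted(missing)}")
    by_driver = contributions.groupby("driver")["volume_million_m3"].sum()
    total = float(by_driver[list(ALL_DRIVERS)].sum())
    passive = float(by_driver[list(PASSIVE_DRIVERS)].sum())
    anthro = float(by_driver[list(ANTHROPOGENIC_DRIVERS)].sum())
    planting = contributions[contributions["driver"] == "planting"]
    planting_total = float(planting["volume_million_m3"].sum())
    reg_shares = {
        r: 100.0 * float(v) / planting_total
        for r, v in planting.groupby("region")["volume_million_m3"].sum().items()
    } if planting_total != 0 else {}
    region_totals = {
        r: float(v) for r, v in
        contributions.groupby("region")["volume_million_m3"].sum().items()
    }
    return ShareReport(
        total_million_m3=total,
        passive_million_m3=passive,
        anthropogenic_million_m3=anthro,
        passive_pct=100.0 * passive / total,
        anthropogenic_pct=100.0 * anthro / total,
        planting_total_million_m3=planting_total,
        planting_regional_share_pct=reg_shares,
        region_totals_million_m3=region_totals,
    )


def carbon_table(
    contributions: pd.DataFrame,
    period_years: Mapping[str, float] | float,
    factors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Driver x region report: million m^3, Tg C, and Tg C per year.

    ``period_years`` is either a single period length or a mapping
    region -> years.
    """
    rows = []
    for row in contributions.itertuples(index=False):
        years = period_years[row.region] if isinstance(period_years, Mapping) \
            else period_years
        tg = volume_to_carbon(row.volume_million_m3, row.region, factors)
        rows.append({
            "region": row.region, "driver": row.driver,
            "volume_million_m3": row.volume_million_m3,
            "carbon_tg": tg,
            "carbon_tg_per_yr": annualize(tg, years),
        })
    return pd.DataFrame(rows)
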