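"""Reference driver-contribution totals for conterminous US forests.

These are the headline regional attribution totals (million m^3 of
aboveground wood volume) from the national-scale application of the
method this package implements, used as inputs to the carbon-reporting
stage for worked examples and reproduction checks.  Desk-scale synthetic
data cannot reproduce them — they derive from the full national plot
inventory — but all downstream carbon arithmetic (Tg C conversions,
annualized rates, passive/anthropogenic shares) recomputes from them.

South covers 12 southern states over 1974-2005 (31 y) and 2005-2022
(17 y); North 21 northern states and West 15 western states over
2005-2022 (17 y; the western censuses end in 2021 but the reference
arithmetic uses the common 17-year period).  The South 2005-2022
temperature and area entries are not reported as period totals at the
source; they are implied by the reported per-year rates and the regional
total and are flagged ``derived=True``.
"""

from __future__ import annotations

import pandas as pd

#: period lengths in years (census-year differences)
PERIOD_YEARS = {(1974, 2005): 31, (2005, 2022): 17}

_ROWS = [
    # region, period, driver, million m^3, derived?
    ("South", (1974, 2005), "area", 230.0, False),
    ("South", (1974, 2005), "age", 601.0, False),
    ("South", (1974, 2005), "temperature", 151.0, False),
    ("South", (1974, 2005), "precipitation", 407.0, False),
    ("South", (1974, 2005), "co2", 616.0, False),
    ("South", (1974, 2005), "planting", 228.0, False),
    ("South", (2005, 2022), "area", -89.0, True),
    ("South", (2005, 2022), "age", 946.0, False),
    ("South", (2005, 2022), "temperature", -102.0, True),
    ("South", (2005, 2022), "precipitation", 328.0, False),
    ("South", (2005, 2022), "co2", 643.0, False),
    ("South", (2005, 2022), "planting", 427.0, False),
]

#: reported regional six-driver totals (million m^3)
REGION_TOTALS = {
    ("South", (1974, 2005)): 2232.0,
    ("South", (2005, 2022)): 2153.0,
    ("North", (2005, 2022)): 1025.0,
    ("West", (2005, 2022)): 54.0,
}

#: reported national driver totals for 2005-2022 (million m^3)
NATIONAL_2005_2022 = {
    "area": -668.0,
    "age": 1949.0,
    "co2": 1432.0,
    "planting": 504.0,
}
NATIONAL_TOTAL_2005_2022 = 3232.0
NATIONAL_PASSIVE_2005_2022 = 1447.0

#: reported unexplained residuals 2005-2022 (million m^3)
UNEXPLAINED_2005_2022 = {"national": -580.0, "North": -507.0}


def south_contributions(period: tuple[int, int]) -> pd.DataFrame:
    """Southern driver contributions for one period (million m^3)."""
    rows = [
        {"region": r, "period_start": p[0], "period_end": p[1],
         "driver": d, "volume_million_m3": v, "derived": flag}
        for r, p, d, v, flag in _ROWS if p == tuple(period)
    ]
    if not rows:
        raise KeyError(f"no reference contributions for period {period}")
    return pd.DataFrame(rows)


def national_contributions_2005_2022() -> pd.DataFrame:
    """National 2005-2022 six-driver table (million m^3), split so the
    planting row carries its regional structure (South vs elsewhere).

    Temperature and precipitation period totals are reported only as the
    combined passive complement (passive - CO2 = 15 million m^3); that
    remainder is carried on the precipitation row with temperature at 0
    so that passive and total sums are exact.
    """
    temp_plus_precip = NATIONAL_PASSIVE_2005_2022 - NATIONAL_2005_2022["co2"]
    south_planting = 427.0
    rows = [
        {"region": "South", "driver": "planting", "volume_million_m3": south_planting},
        {"region": "NorthWest", "driver": "planting",
         "volume_million_m3": NATIONAL_2005_2022["planting"] - south_planting},
        {"region": "National", "driver": "area",
         "volume_million_m3": NATIONAL_2005_2022["area"]},
        {"region": "National", "driver": "age",
         "volume_million_m3": NATIONAL_2005_2022["age"]},
        {"region": "National", "driver": "co2",
         "volume_million_m3": NATIONAL_2005_2022["co2"]},
        {"region": "National", "driver": "temperature", "volume_million_m3": 0.0},
        {"region": "National", "driver": "precipitation",
         "volume_million_m3": temp_plus_precip},
    ]
    return pd.DataFrame(rows)
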