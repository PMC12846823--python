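"""Synthetic inventory, climate and CO2 generators with known ground truth.

Every downstream stage (exposure construction, yield estimation,
counterfactual impacts, attribution, carbon reporting) is tested against
data drawn from a fully specified data-generating process:

- an annual CO2 series interpolated piecewise-exponentially through
  anchor concentrations, calibrated so that 1960-2023 captures 76.5% of
  the rise since 1850;
- county-level seasonal climate with linear trends whose default
  1960-2023 shifts are +15.4 mm winter precipitation and +0.7 degC winter
  temperature (other seasons follow the same qualitative pattern: all
  seasons warm, precipitation rises in every season except fall);
- plot observations whose log volume is the yield model's deterministic
  formula evaluated at the plot's lifetime exposure plus Gaussian noise
  (volumes are positive, so noise is multiplicative log-normal), with
  planted stands receiving an age-dependent volume premium that is ~0 at
  age 10;
- census-style area/age-class inventory tables at two census years whose
  observed volume is the area-weighted expected yield plus an injected
  disturbance shock — the shock is exactly what the attribution stage
  should report as unexplained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import attribution as _attr
from .attribution import InventoryTable, midpoint_age, premium_pool
from .exposure import SEASONS, CO2Index, ClimateIndex, exposure_table
from .yield_model import ModelSpec, YieldResults, climate_columns

PAPER_GROUPS = (
    "Aspen/Birch", "Elm/Ash/Cottonwood", "Loblolly/Shortleaf Pine",
    "Maple/Beech/Birch", "Oak/Gum/Cypress", "Oak/Hickory", "Oak/Pine",
    "Slash/Longleaf Pine", "Spruce/Fir", "White/Red/Jack Pine",
)

MANAGED_GROUPS = (
    "Loblolly/Shortleaf Pine", "Slash/Longleaf Pine", "White/Red/Jack Pine",
)

# seasonal climate normals used as polynomial centres (degC, mm)
DEFAULT_T_CENTERS = {"winter": 2.0, "spring": 10.0, "summer": 22.0, "fall": 12.0}
DEFAULT_P_CENTERS = {"winter": 240.0, "spring": 280.0, "summer": 300.0, "fall": 250.0}


@dataclass(frozen=True)
class GroupParams:
    """True yield parameters of one forest group."""

    intercept: float
    theta: float  # coefficient on -1/age (Clutter age curve)
    # planting premium knots (age, m^3/ha); empty = unmanaged group
    premium_knots: tuple[tuple[float, float], ...] = ()


def _interp_knots(knots, age: float) -> float:
    if not knots or age < 10:
        return 0.0
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    return float(np.interp(age, xs, ys))


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth parameter set of the synthetic data-generating process."""

    groups: Mapping[str, GroupParams]
    temp_coefs: Mapping[str, tuple[float, float, float]]  # season -> cubic coefs
    prcp_coefs: Mapping[str, tuple[float, float, float]]
    gamma: float  # CO2 elasticity
    noise_sd: float  # SD of log-volume noise
    t_centers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_T_CENTERS))
    p_centers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_CENTERS))

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g, gp in self.groups.items():
            if abs(_interp_knots(gp.premium_knots, 10.0)) > 1e-9:
                raise ValueError(f"planting premium at age 10 must be ~0 (group {g})")

    def premium(self, group: str, age: float) -> float:
        """Planted-minus-natural volume premium (m^3/ha); 0 below age 10."""
        gp = self.groups.get(group)
        return _interp_knots(gp.premium_knots, age) if gp else 0.0

    def centers(self) -> dict[str, float]:
        out = {f"T_{s}": self.t_centers[s] for s in SEASONS}
        out.update({f"P_{s}": self.p_centers[s] for s in SEASONS})
        return out

    def coefficients(self) -> dict[str, float]:
        """True coefficients keyed by the yield model's design-column names."""
        p: dict[str, float] = {}
        for g, gp in self.groups.items():
            p[f"alpha[{g}]"] = gp.intercept
            p[f"neg_inv_age[{g}]"] = gp.theta
        for s in SEASONS:
            for k in (1, 2, 3):
                p[f"T_{s}^{k}"] = self.temp_coefs[s][k - 1]
                p[f"P_{s}^{k}"] = self.prcp_coefs[s][k - 1]
        p["log_co2"] = self.gamma
        return p

    def to_results(self, age_range: tuple[int, int] = (1, 200)) -> YieldResults:
        """YieldResults carrying the true coefficients (identity covariance)."""
        spec = ModelSpec(age_form="clutter", origin_filter=None,
                         groups=tuple(self.groups), age_range=age_range,
                         climate_centers=self.centers())
        return YieldResults.from_coefficients(
            self.coefficients(), self.centers(), tuple(sorted(self.groups)), spec=spec
        )

    @classmethod
    def default(cls, gamma: float = 1.1, noise_sd: float = 0.5) -> "TrueParams":
        """The study-condition parameter set used throughout the tests."""
        intercepts = [-1.9, -1.7, -1.1, -1.8, -1.4, -1.5, -1.6, -1.2, -2.1, -1.65]
        thetas = [14.0, 12.0, 9.0, 16.0, 11.0, 13.0, 12.5, 9.5, 18.0, 15.0]
        premiums = {
            "Loblolly/Shortleaf Pine": ((10, 0.0), (20, 35.0), (30, 70.0), (40, 98.6), (50, 110.0)),
            "Slash/Longleaf Pine": ((10, 0.0), (20, 20.0), (30, 40.0), (40, 57.6), (50, 65.0)),
            "White/Red/Jack Pine": ((10, 0.0), (20, 25.0), (30, 50.0), (40, 77.3), (50, 85.0)),
        }
        groups = {
            name: GroupParams(a, t, premiums.get(name, ()))
            for name, a, t in zip(PAPER_GROUPS, intercepts, thetas)
        }
        temp = {
            "winter": (0.030, -0.008, 0.0010),
            "spring": (0.022, -0.006, 0.0008),
            "summer": (-0.015, -0.010, 0.0006),
            "fall": (0.018, -0.005, 0.0007),
        }
        prcp = {
            "winter": (0.060, -0.020, 0.004),
            "spring": (0.050, -0.015, 0.003),
            "summer": (0.070, -0.025, 0.005),
            "fall": (0.040, -0.012, 0.002),
        }
        return cls(groups=groups, temp_coefs=temp, prcp_coefs=prcp,
                   gamma=gamma, noise_sd=noise_sd)


# -- CO2 --------------------------------------------------------------------

#: anchors calibrated so (C2023-C1960)/(C2023-C1850) = 0.765 exactly
DEFAULT_CO2_ANCHORS = {1850: 285.0, 1960: 419.0 - 0.765 * (419.0 - 285.0), 2023: 419.0}


def generate_co2(
    year_range: tuple[int, int] = (1850, 2023),
    anchors: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Annual CO2 series through anchor concentrations (piecewise exponential).

    Between consecutive anchors the concentration grows at a constant
    relative rate.  Default anchors are calibrated so the 1960-2023 rise
    is 76.5% of the post-1850 rise.  Anchors must be non-decreasing in
    concentration and strictly positive.
    """
    anchors = dict(DEFAULT_CO2_ANCHORS if anchors is None else anchors)
    yrs = sorted(anchors)
    if len(yrs) < 2:
        raise ValueError("need at least two anchors")
    vals = [anchors[y] for y in yrs]
    if min(vals) <= 0:
        raise ValueError("anchor concentrations must be positive")
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("anchor concentrations must be non-decreasing "
                         "(invalid calibration)")
    y0, y1 = year_range
    if y0 < yrs[0] or y1 > yrs[-1]:
        raise ValueError(f"year range {year_range} outside anchor span [{yrs[0]}, {yrs[-1]}]")
    years = np.arange(y0, y1 + 1)
    # exponential interpolation = linear interpolation of log concentration
    conc = np.exp(np.interp(years, yrs, np.log(vals)))
    return pd.DataFrame({"year": years, "co2_ppm": conc})


# -- climate ----------------------------------------------------------------


@dataclass(frozen=True)
class ClimateTrendSpec:
    """Linear seasonal climate trends and noise for the climate generator.

    ``temp_delta``/``prcp_delta`` give the expected change of each
    season's mean over the trend window (default 1960-2023, the study's
    comparison window), in degC and mm.
    """

    temp_delta: Mapping[str, float] = field(default_factory=lambda: {
        "winter": 0.7, "spring": 0.5, "summer": 0.4, "fall": 0.5})
    prcp_delta: Mapping[str, float] = field(default_factory=lambda: {
        "winter": 15.4, "spring": 8.0, "summer": 5.0, "fall": -3.0})
    temp_noise_sd: float = 0.9
    prcp_noise_sd: float = 45.0
    baseline_t_sd: float = 3.0
    baseline_p_sd: float = 60.0
    trend_window: tuple[int, int] = (1960, 2023)


def generate_climate(
    locations: Sequence[str],
    year_range: tuple[int, int] = (1850, 2023),
    trend: ClimateTrendSpec = ClimateTrendSpec(),
    seed: int = 0,
    t_centers: Mapping[str, float] = DEFAULT_T_CENTERS,
    p_centers: Mapping[str, float] = DEFAULT_P_CENTERS,
) -> pd.DataFrame:
    """County-level seasonal climate with linear trends plus white noise.

    Each location draws a time-invariant seasonal baseline around the
    seasonal normals; each season then follows a linear trend sized so
    the expected change across the trend window matches the configured
    deltas.  Precipitation is floored at zero.
    """
    if len(locations) == 0:
        raise ValueError("need at least one location")
    rng = np.random.default_rng(seed)
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    ny, nl = len(years), len(locations)
    w0, w1 = trend.trend_window
    span = w1 - w0
    frames = []
    for s in SEASONS:
        base_t = rng.normal(t_centers[s], trend.baseline_t_sd, nl)
        base_p = np.maximum(rng.normal(p_centers[s], trend.baseline_p_sd, nl), 30.0)
        slope_t = trend.temp_delta[s] / span
        slope_p = trend.prcp_delta[s] / span
        # (locations x years) grids
        t = base_t[:, None] + slope_t * (years - w0)[None, :] \
            + rng.normal(0, trend.temp_noise_sd, (nl, ny))
        p = base_p[:, None] + slope_p * (years - w0)[None, :] \
            + rng.normal(0, trend.prcp_noise_sd, (nl, ny))
        frames.append(pd.DataFrame({
            "location": np.repeat(locations, ny),
            "season": s,
            "year": np.tile(years, nl),
            "tmean_c": t.ravel(),
            "prcp_mm": np.maximum(p, 0.0).ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


# -- plots ------------------------------------------------------------------


def generate_plots(
    true_params: TrueParams,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
    n_per_group: int = 500,
    age_range: tuple[int, int] = (1, 100),
    planted_age_range: tuple[int, int] = (1, 50),
    year_range: tuple[int, int] = (1968, 2023),
    planted_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """FIA-like plot observations from the true yield process.

    Log volume is the deterministic yield formula evaluated at each
    plot's lifetime exposure plus N(0, noise_sd) noise; planted plots
    (drawn only within managed groups, ages capped at the rotation
    range) additionally receive the true planting premium.  Raises if
    any plot's exposure window falls outside climate/CO2 coverage.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    rng = np.random.default_rng(seed)
    locations = list(cidx.locations)
    rows = []
    for g, gp in true_params.groups.items():
        managed = len(gp.premium_knots) > 0
        for _ in range(n_per_group):
            planted = managed and (rng.random() < planted_fraction)
            lo, hi = planted_age_range if planted else age_range
            rows.append({
                "location": locations[rng.integers(len(locations))],
                "group": g,
                "origin": "planted" if planted else "natural",
                "age": int(rng.integers(lo, hi + 1)),
                "year": int(rng.integers(year_range[0], year_range[1] + 1)),
            })
    plots = pd.DataFrame(rows)
    plots.insert(0, "plot_id", [f"p{i:06d}" for i in range(len(plots))])

    expo = exposure_table(plots, cidx, xidx)
    truth = true_params.to_results()
    lp = _linear_predictor_vec(truth, plots, expo)
    vol_det = np.exp(lp)
    prem = np.array([
        true_params.premium(g, a) if o == "planted" else 0.0
        for g, a, o in zip(plots["group"], plots["age"], plots["origin"])
    ])
    noise = rng.normal(0.0, true_params.noise_sd, len(plots)) if true_params.noise_sd > 0 \
        else np.zeros(len(plots))
    plots["volume_m3ha"] = (vol_det + prem) * np.exp(noise)
    return plots


def _linear_predictor_vec(results: YieldResults, plots: pd.DataFrame,
                          expo: pd.DataFrame) -> np.ndarray:
    """Vectorised linear predictor of a YieldResults over a plot table."""
    p = results.params
    c = results.centers
    lp = np.zeros(len(plots))
    age = plots["age"].to_numpy(dtype=float)
    for g in results.groups:
        mask = (plots["group"] == g).to_numpy()
        if mask.any():
            lp[mask] += float(p[f"alpha[{g}]"]) + float(p[f"neg_inv_age[{g}]"]) * (-1.0 / age[mask])
    from .yield_model import P_SCALE, T_SCALE
    for s in SEASONS:
        t = (expo[f"T_{s}"].to_numpy() - c[f"T_{s}"]) / T_SCALE
        pr = (expo[f"P_{s}"].to_numpy() - c[f"P_{s}"]) / P_SCALE
        for k in (1, 2, 3):
            lp += float(p[f"T_{s}^{k}"]) * t ** k
            lp += float(p[f"P_{s}^{k}"]) * pr ** k
    lp += float(p["log_co2"]) * np.log(expo["co2_mean"].to_numpy())
    return lp


# -- census inventory -------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """Structure of a synthetic region's census tables."""

    name: str = "South"
    location: str = "c00"  # climate location standing in for the region
    groups: tuple[str, ...] = ("Loblolly/Shortleaf Pine", "Oak/Hickory")
    age_classes: tuple[tuple[int, int], ...] = (
        (1, 10), (11, 20), (21, 30), (31, 40), (41, 50),
        (51, 60), (61, 70), (71, 80), (81, 90), (91, 100),
    )
    planted_share: float = 0.3  # planted share of area in managed-group classes <= 50 y
    mean_cell_area_ha: float = 2.0e5


def generate_inventory(
    true_params: TrueParams,
    region: RegionSpec,
    climate: pd.DataFrame | ClimateIndex,
    co2: pd.DataFrame | CO2Index,
    census_years: tuple[int, int] = (2005, 2022),
    seed: int = 0,
    shock: float = 0.0,
) -> tuple[InventoryTable, InventoryTable]:
    """Two census inventories whose observed volume embeds a known shock.

    Areas are random but non-negative; each census's observed volume per
    group is exactly the area-weighted expected yield (true yield at the
    age-class midpoint under that census year's lifetime exposures, plus
    the planting premium on planted cells).  ``shock`` (m^3) is added to
    the end census's observed volume only, so a correctly specified
    decomposition must report it as the unexplained residual.
    """
    classes = sorted(region.age_classes)
    for (lo1, hi1), (lo2, hi2) in zip(classes, classes[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping age classes [{lo1},{hi1}] and [{lo2},{hi2}]")
    cidx = climate if isinstance(climate, ClimateIndex) else ClimateIndex(climate)
    xidx = co2 if isinstance(co2, CO2Index) else CO2Index(co2)
    rng = np.random.default_rng(seed)
    truth = true_params.to_results()

    def make_areas(scale_draw) -> pd.DataFrame:
        rows = []
        for g in region.groups:
            managed = len(true_params.groups[g].premium_knots) > 0
            for lo, hi in region.age_classes:
                total = scale_draw()
                p_share = region.planted_share if (managed and hi <= 50) else 0.0
                if p_share > 0:
                    rows.append({"group": g, "age_lo": lo, "age_hi": hi,
                                 "origin": "planted", "area_ha": total * p_share})
                rows.append({"group": g, "age_lo": lo, "age_hi": hi,
                             "origin": "natural", "area_ha": total * (1 - p_share)})
        return pd.DataFrame(rows)

    areas1 = make_areas(lambda: region.mean_cell_area_ha * rng.lognormal(0.0, 0.4))
    drift = lambda: float(rng.uniform(0.8, 1.3))  # noqa: E731
    areas2 = areas1.copy()
    areas2["area_ha"] = areas1["area_ha"] * [drift() for _ in range(len(areas1))]

    def observed(areas: pd.DataFrame, year: int, add_shock: float) -> pd.DataFrame:
        vols = {}
        for g in region.groups:
            sub = areas[areas["group"] == g]
            base = _attr._base_stock(truth, sub, cidx, xidx, region.location,
                                     temp_year=year, precip_year=year, co2_year=year)
            vols[g] = base + premium_pool(sub, true_params.premium)
        total = sum(vols.values())
        return pd.DataFrame({
            "group": list(vols),
            "volume_m3": [v + add_shock * (v / total if total else 0.0) for v in vols.values()],
        })

    y1, y2 = census_years
    inv1 = InventoryTable(region.name, y1, areas1, observed(areas1, y1, 0.0))
    inv2 = InventoryTable(region.name, y2, areas2, observed(areas2, y2, shock))
    return inv1, inv2


def write_scenario_csvs(out_dir, plots, climate, co2, inventories=None) -> None:
    """Write the generator outputs as the pipeline's four CSV inputs."""
    import pathlib
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plots.to_csv(out / "plots.csv", index=False)
    climate.to_csv(out / "climate.csv", index=False)
    co2.to_csv(out / "co2.csv", index=False)
    if inventories is not None:
        frames = []
        for inv in inventories:
            a = inv.areas.copy()
            a.insert(0, "region", inv.region)
            a.insert(1, "census_year", inv.year)
            obs = inv.observed_volume.set_index("group")["volume_m3"]
            a["observed_volume_m3"] = [
                obs[g] if (g in obs.index) else np.nan for g in a["group"]
            ]
            frames.append(a)
        pd.concat(frames, ignore_index=True).to_csv(out / "inventory.csv", index=False)
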