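"""Canonical simulation experiments on the synthetic study conditions.

These are the package's standing validation experiments, shared by the
test suite and the reproduction script:

- **gamma recovery**: repeated draw-and-refit of the study-condition
  data-generating process; the fitted CO2 elasticity's 95% confidence
  interval should cover the true value in ~95% of replicates;
- **F-test type-I error**: the seasonal-polynomial Wald F-test under a
  null DGP (all climate coefficients zero) should reject at ~5%;
- **decomposition additivity**: on random toy inventories, the six
  telescoped contributions must sum exactly to the explained change and
  the unexplained residual must equal the injected disturbance shock;
- **reorder oracle**: telescoping contributions must match a brute-force
  evaluation of successive stock differences over all 720 driver orders.

Study conditions: 5,000 plots (500 per group for the 10 modelled forest
groups) spread over 800 counties — FIA-like sparsity of a handful of
same-group plots per county — log-volume noise SD 0.5, CO2 elasticity
1.1.  Counties matter: the climate polynomials are identified almost
entirely cross-county, so the county count, not the plot count, is the
effective sample for their covariance.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import attribution as attr
from .attribution import DRIVERS, InventoryTable, premium_pool
from .exposure import SEASONS, CO2Index, ClimateIndex
from .synthetic import (
    RegionSpec,
    TrueParams,
    generate_climate,
    generate_co2,
    generate_inventory,
    generate_plots,
)
from .yield_model import YieldModel, YieldResults

STUDY_N_LOCATIONS = 800
STUDY_N_PER_GROUP = 500  # x 10 groups = 5,000 plots
STUDY_GAMMA = 1.1
STUDY_NOISE_SD = 0.5


def _locations(n: int = STUDY_N_LOCATIONS) -> list[str]:
    return [f"c{i:04d}" for i in range(n)]


def _rep_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % 2**31]


def _null_params() -> TrueParams:
    base = TrueParams.default(gamma=STUDY_GAMMA, noise_sd=STUDY_NOISE_SD)
    zero = {s: (0.0, 0.0, 0.0) for s in SEASONS}
    return TrueParams(groups=base.groups, temp_coefs=zero, prcp_coefs=zero,
                      gamma=base.gamma, noise_sd=base.noise_sd)


def gamma_recovery(n_reps: int = 50, seed: int = 0) -> pd.DataFrame:
    """Refit the CO2 elasticity on fresh study-condition draws.

    Returns one row per replicate with the estimate, its 95% CI and
    whether the CI covers the true elasticity.
    """
    truth = TrueParams.default(gamma=STUDY_GAMMA, noise_sd=STUDY_NOISE_SD)
    co2 = generate_co2()
    locs = _locations()
    seeds = _rep_seeds(seed, 2 * n_reps)
    rows = []
    for r in range(n_reps):
        climate = generate_climate(locs, seed=seeds[2 * r])
        plots = generate_plots(truth, climate, co2,
                               n_per_group=STUDY_N_PER_GROUP, seed=seeds[2 * r + 1])
        res = YieldModel.from_tables(plots, climate, co2).fit()
        lo, hi = res.conf_int("log_co2")
        rows.append({"rep": r, "gamma_hat": res.co2_elasticity,
                     "ci_lo": lo, "ci_hi": hi,
                     "covered": lo <= truth.gamma <= hi})
    return pd.DataFrame(rows)


def ftest_type1(
    n_reps: int = 100,
    seed: int = 0,
    season: str = "winter",
    variable: str = "temperature",
) -> pd.DataFrame:
    """Seasonal-polynomial F-test under the null DGP (no climate effect)."""
    truth = _null_params()
    co2 = generate_co2()
    locs = _locations()
    seeds = _rep_seeds(seed + 1, 2 * n_reps)
    rows = []
    for r in range(n_reps):
        climate = generate_climate(locs, seed=seeds[2 * r])
        plots = generate_plots(truth, climate, co2,
                               n_per_group=STUDY_N_PER_GROUP, seed=seeds[2 * r + 1])
        res = YieldModel.from_tables(plots, climate, co2).fit()
        F, p = res.f_test_seasonal_poly(season, variable)
        rows.append({"rep": r, "F": F, "p": p, "reject_05": p < 0.05})
    return pd.DataFrame(rows)


def decomposition_additivity(n_inventories: int = 100, seed: int = 0) -> pd.DataFrame:
    """Additivity and shock recovery on random toy inventories.

    Each replicate draws a fresh two-group census pair with a random
    disturbance shock injected into the end census, decomposes with the
    true yield parameters, and records (i) the gap between the summed
    contributions and an independently evaluated end-minus-start stock
    difference and (ii) the gap between the unexplained residual and the
    injected shock.
    """
    truth_params = TrueParams.default(noise_sd=0.0)
    truth = truth_params.to_results()
    co2 = generate_co2()
    climate = generate_climate(["c00", "c01"], seed=seed + 99)
    cidx, xidx = ClimateIndex(climate), CO2Index(co2)
    group_pool = list(truth_params.groups)
    rng = np.random.default_rng(seed)
    seeds = _rep_seeds(seed + 2, n_inventories)
    rows = []
    for r in range(n_inventories):
        groups = tuple(rng.choice(group_pool, size=2, replace=False))
        region = RegionSpec(name="Toy", location="c00", groups=groups)
        shock = float(rng.uniform(-1e8, 1e8))
        inv1, inv2 = generate_inventory(truth_params, region, cidx, xidx,
                                        seed=seeds[r], shock=shock)
        result = attr.decompose(truth, inv1, inv2, cidx, xidx,
                                truth_params.premium, location="c00")
        contrib_sum = sum(result.contributions.values()) * 1e6
        direct = _direct_stock_difference(truth, inv1, inv2, cidx, xidx,
                                          truth_params.premium, "c00")
        scale = max(abs(direct), 1.0)
        rows.append({
            "rep": r,
            "shock_m3": shock,
            "additivity_rel_err": abs(contrib_sum - direct) / scale,
            "shock_rel_err": abs(result.unexplained * 1e6 - shock) / max(abs(shock), 1.0),
        })
    return pd.DataFrame(rows)


def _direct_stock_difference(results, inv1, inv2, cidx, xidx, premium, location):
    """End-minus-start stock via direct aggregate_volume calls (oracle path)."""
    v1 = attr.aggregate_volume(results, inv1.areas, cidx, xidx, location=location,
                               temp_year=inv1.year, precip_year=inv1.year,
                               co2_year=inv1.year, planting=True, premium=premium)
    v2 = attr.aggregate_volume(results, inv2.areas, cidx, xidx, location=location,
                               temp_year=inv2.year, precip_year=inv2.year,
                               co2_year=inv2.year, planting=True, premium=premium)
    return v2 - v1


def _brute_force_contributions(
    results: YieldResults,
    inv1: InventoryTable,
    inv2: InventoryTable,
    cidx: ClimateIndex,
    xidx: CO2Index,
    premium,
    location: str,
    order,
    cache: dict | None = None,
) -> dict[str, float]:
    """Successive stock differences evaluated from scratch (no shared cache).

    Rebuilds every intermediate driver state explicitly: per-group area
    totals from the 'area' census, age/origin shares from the 'age'
    census, exposure-window end years from the climate-driver censuses,
    and the planting premium pool from the 'planting' census.
    """
    inv = {"start": inv1, "end": inv2}
    cache = {} if cache is None else cache

    def areas_for(area_state, age_state):
        tot = inv[area_state].areas.groupby("group")["area_ha"].sum()
        a = inv[age_state].areas.copy()
        tot_age = a.groupby("group")["area_ha"].transform("sum")
        a["area_ha"] = a["area_ha"] / tot_age * tot.reindex(a["group"]).to_numpy()
        return a

    def stock(state):
        # stock is a pure function of the driver-state corner; memoize corners
        key = tuple(state[d] for d in DRIVERS)
        if key not in cache:
            areas = areas_for(state["area"], state["age"])
            base = attr.aggregate_volume(
                results, areas, cidx, xidx, location=location,
                temp_year=inv[state["temperature"]].year,
                precip_year=inv[state["precipitation"]].year,
                co2_year=inv[state["co2"]].year, planting=False,
            )
            cache[key] = base + premium_pool(inv[state["planting"]].areas, premium)
        return cache[key]

    state = {d: "start" for d in DRIVERS}
    prev = stock(state)
    out = {}
    for d in order:
        state[d] = "end"
        cur = stock(state)
        out[d] = cur - prev
        prev = cur
    return out


def reorder_oracle(seed: int = 0, n_orders: int | None = None) -> pd.DataFrame:
    """Compare telescoping contributions with brute force over driver orders.

    On a two-group toy inventory pair, evaluates every driver order
    (all 720 by default) both through `reorder_sensitivity` and through
    an independent from-scratch evaluation of the successive stock
    differences, and reports the worst absolute disagreement per driver
    plus the spread of the explained total across orders.
    """
    truth_params = TrueParams.default(noise_sd=0.0)
    truth = truth_params.to_results()
    co2 = generate_co2()
    climate = generate_climate(["c00", "c01"], seed=seed + 7)
    cidx, xidx = ClimateIndex(climate), CO2Index(co2)
    region = RegionSpec(name="Toy", location="c00",
                        groups=("Loblolly/Shortleaf Pine", "Oak/Hickory"))
    inv1, inv2 = generate_inventory(truth_params, region, cidx, xidx,
                                    seed=seed + 11, shock=0.0)
    orders = list(itertools.permutations(DRIVERS))
    if n_orders is not None:
        orders = orders[:n_orders]
    bf = {d: [] for d in DRIVERS}
    bf_explained = []
    corner_cache: dict = {}
    for order in orders:
        contrib = _brute_force_contributions(truth, inv1, inv2, cidx, xidx,
                                             truth_params.premium, "c00", order,
                                             cache=corner_cache)
        for d in DRIVERS:
            bf[d].append(contrib[d])
        bf_explained.append(sum(contrib.values()))
    rs = attr.reorder_sensitivity(truth, inv1, inv2, cidx, xidx,
                                  truth_params.premium, location="c00",
                                  permutations=orders)
    M = 1e6
    rows = []
    for i, d in enumerate(DRIVERS):
        rows.append({
            "driver": d,
            "bf_min_million_m3": min(bf[d]) / M,
            "bf_max_million_m3": max(bf[d]) / M,
            "min_gap_million_m3": abs(min(bf[d]) / M - rs["min_million_m3"][i]),
            "max_gap_million_m3": abs(max(bf[d]) / M - rs["max_million_m3"][i]),
        })
    out = pd.DataFrame(rows)
    out.attrs["explained_spread_million_m3"] = (max(bf_explained) - min(bf_explained)) / M
    out.attrs["n_orders"] = len(orders)
    return out
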