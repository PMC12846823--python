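"""Pipeline stages tying the modules together (simulate -> ... -> report).

Each stage reads its inputs from, and writes its outputs to, one
artifact directory, so stages can be run individually from the CLI or
end-to-end with :func:`run_pipeline`.  Every run stamps a
``pipeline.json`` with the configuration hash and seed; identical
configurations yield byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import attribution as attr
from . import carbon as carbon_mod
from . import counterfactual as cf
from . import planting as plant
from . import synthetic as syn
from .config import PipelineConfig
from .exposure import CO2Index, ClimateIndex
from .yield_model import ModelSpec, YieldModel, YieldResults

log = logging.getLogger("forestsink")

STAGES = ("simulate", "fit", "impact", "planting", "attribute", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stamp(cfg: PipelineConfig, out: pathlib.Path) -> None:
    with open(out / "pipeline.json", "w") as fh:
        json.dump({"config_hash": cfg.config_hash(), "seed": cfg.seed}, fh, indent=1)
    cfg.to_yaml(out / "config_used.yaml")


def _read_inputs(out: pathlib.Path):
    climate = pd.read_csv(out / "climate.csv")
    co2 = pd.read_csv(out / "co2.csv")
    plots = pd.read_csv(out / "plots.csv")
    return plots, ClimateIndex(climate), CO2Index(co2)


def _read_inventories(out: pathlib.Path, cfg: PipelineConfig):
    df = pd.read_csv(out / "inventory.csv")
    invs = []
    for year in cfg.scenario.census_years:
        sub = df[df["census_year"] == year]
        areas = sub[["group", "age_lo", "age_hi", "origin", "area_ha"]].reset_index(drop=True)
        obs = sub.groupby("group")["observed_volume_m3"].first().reset_index()
        obs.columns = ["group", "volume_m3"]
        invs.append(attr.InventoryTable(cfg.scenario.region, int(year), areas, obs))
    return invs


def simulate(cfg: PipelineConfig, out: pathlib.Path) -> None:
    s = cfg.scenario
    rng_seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    seeds = [int(ss.generate_state(1)[0] % 2**31) for ss in rng_seeds]
    locations = [f"c{i:02d}" for i in range(s.n_locations)]
    co2 = syn.generate_co2(s.year_range)
    climate = syn.generate_climate(locations, s.year_range, seed=seeds[0])
    tp = syn.TrueParams.default(gamma=s.gamma, noise_sd=s.noise_sd)
    plots = syn.generate_plots(
        tp, climate, co2, n_per_group=s.n_plots_per_group,
        year_range=s.plot_year_range, planted_fraction=s.planted_fraction,
        seed=seeds[1],
    )
    region = syn.RegionSpec(name=s.region, location=s.region_location,
                            groups=s.region_groups)
    invs = syn.generate_inventory(
        tp, region, climate, co2, census_years=s.census_years,
        seed=seeds[2], shock=s.shock_million_m3 * 1e6,
    )
    syn.write_scenario_csvs(out, plots, climate, co2, invs)
    log.info("simulate: %d plots, %d locations, shock %.0f million m^3",
             len(plots), s.n_locations, s.shock_million_m3)


def fit(cfg: PipelineConfig, out: pathlib.Path) -> YieldResults:
    plots, cidx, xidx = _read_inputs(out)
    m = cfg.model
    spec = ModelSpec(age_form=m.age_form, origin_filter=m.origin_filter,
                     age_range=m.age_range, fixed_effects=m.fixed_effects)
    res = YieldModel.from_tables(plots, cidx, xidx, spec).fit()
    res.to_json(out / "model.json")
    (out / "model_summary.txt").write_text(res.summary() + "\n")
    log.info("fit: n=%d, gamma=%.3f", res.nobs, res.co2_elasticity)
    return res


def impact(cfg: PipelineConfig, out: pathlib.Path) -> pd.DataFrame:
    plots, cidx, xidx = _read_inputs(out)
    res = YieldResults.from_json(out / "model.json")
    ic = cfg.impact
    subsets = [("temperature",), ("precipitation",), ("co2",),
               ("temperature", "precipitation", "co2")]
    table = cf.impact_table(res, ic.group, sorted(plots["location"].unique()),
                            ic.ages, subsets, ic.base_year, ic.eval_year, cidx, xidx)
    table.to_csv(out / "impact.csv", index=False)
    cf.impact_summary(table).to_csv(out / "impact_summary.csv", index=False)
    log.info("impact: %d cells", len(table))
    return table


def planting(cfg: PipelineConfig, out: pathlib.Path) -> pd.DataFrame:
    plots, _, _ = _read_inputs(out)
    groups = [g for g in plant.MANAGED_GROUPS
              if (plots[plots["group"] == g]["origin"] == "planted").any()]
    rows = []
    for g in groups:
        for d in plant.DECADES:
            try:
                rows.append(vars(plant.compare_planted_natural(plots, g, d)))
            except ValueError as exc:  # thin decade cell in a small scenario
                log.warning("skipping %s decade %d: %s", g, d, exc)
    if not rows:
        raise ValueError("no group x decade cell has enough plots of both origins")
    table = pd.DataFrame(rows)
    table.to_csv(out / "planting.csv", index=False)
    plant.premium_schedule(table).to_frame().to_csv(out / "premium.csv", index=False)
    log.info("planting: %d comparisons", len(table))
    return table


def attribute(cfg: PipelineConfig, out: pathlib.Path) -> attr.AttributionResult:
    _, cidx, xidx = _read_inputs(out)
    res = YieldResults.from_json(out / "model.json")
    premium = plant.premium_schedule(pd.read_csv(out / "planting.csv"))
    inv1, inv2 = _read_inventories(out, cfg)
    result = attr.decompose(res, inv1, inv2, cidx, xidx, premium,
                            location=cfg.scenario.region_location,
                            order=cfg.attribution.order)
    result.to_frame().to_csv(out / "attribution.csv", index=False)
    (out / "attribution_summary.txt").write_text(result.summary() + "\n")
    log.info("attribute: explained %.1f, unexplained %.1f million m^3",
             result.explained, result.unexplained)
    return result


def report(cfg: PipelineConfig, out: pathlib.Path) -> pd.DataFrame:
    contrib = pd.read_csv(out / "attribution.csv")
    contrib = contrib[contrib["driver"].isin(attr.DRIVERS)]
    years = {cfg.scenario.region:
             cfg.scenario.census_years[1] - cfg.scenario.census_years[0]}
    factors = dict(cfg.carbon.factors)
    table = carbon_mod.carbon_table(contrib, years, factors)
    table.to_csv(out / "report.csv", index=False)
    share = carbon_mod.share_report(contrib)
    lines = [share.summary(), "", table.to_string(index=False)]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    log.info("report: passive share %.1f%%", share.passive_pct)
    return table


_STAGE_FN = {
    "simulate": simulate, "fit": fit, "impact": impact,
    "planting": planting, "attribute": attribute, "report": report,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        _STAGE_FN[name](cfg, out)
    except KeyError:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}") from None
    except Exception as exc:  # abort with stage name and cause
        raise StageError(name, exc) from exc
    _stamp(cfg, out)


def run_pipeline(cfg: PipelineConfig, out_dir) -> pathlib.Path:
    """Run all stages in dependency order; returns the artifact directory."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in STAGES:
        log.info("running stage %s", name)
        run_stage(name, cfg, out)
    return out
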