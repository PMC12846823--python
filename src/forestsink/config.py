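"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .attribution import DRIVERS
from .carbon import DEFAULT_CARBON_FACTORS


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Strict):
    """Synthetic-scenario controls: sample sizes, trends, truth, censuses."""

    n_locations: int = 12
    year_range: tuple[int, int] = (1850, 2023)
    n_plots_per_group: int = 300
    plot_year_range: tuple[int, int] = (1968, 2023)
    planted_fraction: float = 0.3
    gamma: float = 1.1
    noise_sd: float = 0.5
    census_years: tuple[int, int] = (2005, 2022)
    shock_million_m3: float = -50.0
    region: str = "South"
    region_location: str = "c00"
    region_groups: tuple[str, ...] = ("Loblolly/Shortleaf Pine", "Oak/Hickory")


class ModelConfig(_Strict):
    """Yield-regression specification."""

    age_form: Literal["clutter", "log", "cubic"] = "clutter"
    origin_filter: Literal["natural", "planted"] | None = "natural"
    age_range: tuple[int, int] = (1, 150)
    fixed_effects: Literal["period", "year"] | None = None


class ImpactConfig(_Strict):
    """Counterfactual impact stage: comparison years and evaluation ages."""

    base_year: int = 1960
    eval_year: int = 2023
    ages: tuple[int, ...] = (25, 100)
    group: str = "Oak/Hickory"


class AttributionConfig(_Strict):
    order: tuple[str, ...] = DRIVERS

    @field_validator("order")
    @classmethod
    def _perm(cls, v):
        if sorted(v) != sorted(DRIVERS):
            raise ValueError(f"order must be a permutation of {DRIVERS}")
        return v


class CarbonConfig(_Strict):
    factors: Mapping[str, float] = dict(DEFAULT_CARBON_FACTORS)


class PipelineConfig(_Strict):
    """Full configuration of the simulate->fit->...->report pipeline."""

    seed: int = 0
    scenario: ScenarioConfig = ScenarioConfig()
    model: ModelConfig = ModelConfig()
    impact: ImpactConfig = ImpactConfig()
    attribution: AttributionConfig = AttributionConfig()
    carbon: CarbonConfig = CarbonConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]
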