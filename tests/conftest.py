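import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import forestsink as fs

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def co2_default() -> pd.DataFrame:
    return fs.generate_co2()


@pytest.fixture(scope="session")
def climate_small() -> pd.DataFrame:
    return fs.generate_climate([f"c{i:02d}" for i in range(6)], seed=42)


@pytest.fixture(scope="session")
def true_params() -> fs.TrueParams:
    return fs.TrueParams.default()


@pytest.fixture(scope="session")
def truth_results(true_params) -> fs.YieldResults:
    return true_params.to_results()


@pytest.fixture(scope="session")
def plots_small(true_params, climate_small, co2_default) -> pd.DataFrame:
    return fs.generate_plots(
        true_params, climate_small, co2_default,
        n_per_group=120, planted_fraction=0.4, seed=3,
    )


@pytest.fixture(scope="session")
def constant_climate() -> pd.DataFrame:
    """One location, every season/year at fixed values (T=7 degC, P=200 mm)."""
    years = np.arange(1850, 2024)
    frames = []
    for s in fs.SEASONS:
        frames.append(pd.DataFrame({
            "location": "flat", "season": s, "year": years,
            "tmean_c": 7.0, "prcp_mm": 200.0,
        }))
    return pd.concat(frames, ignore_index=True)
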