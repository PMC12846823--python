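"""Synthetic generators: CO2 calibration, climate trends, plot DGP, inventories."""

import numpy as np
import pandas as pd
import pytest

import forestsink as fs
from forestsink.yield_model import P_SCALE, T_SCALE


class TestCO2Generator:
    def test_default_fraction_of_post_1850_rise(self):
        """1960-2023 captures 76.5% (+-0.01) of the CO2 rise since 1850."""
        c = fs.generate_co2().set_index("year")["co2_ppm"]
        frac = (c[2023] - c[1960]) / (c[2023] - c[1850])
        assert frac == pytest.approx(0.765, abs=0.01)
        assert (np.diff(c.to_numpy()) >= -1e-12).all()  # non-decreasing

    def test_constant_anchors_give_flat_series(self):
        c = fs.generate_co2((1900, 1950), {1900: 300.0, 1950: 300.0})
        assert np.allclose(c["co2_ppm"], 300.0)

    def test_two_anchor_exponential_midpoint(self):
        """Piecewise-exponential interpolation matches the closed form."""
        c = fs.generate_co2((2000, 2010), {2000: 300.0, 2010: 400.0})
        expected = 300.0 * (400.0 / 300.0) ** 0.5
        assert c.set_index("year").loc[2005, "co2_ppm"] == pytest.approx(expected, rel=1e-12)

    def test_decreasing_anchors_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            fs.generate_co2((1900, 2000), {1900: 350.0, 2000: 300.0})

    def test_range_outside_anchor_span_rejected(self):
        with pytest.raises(ValueError):
            fs.generate_co2((1800, 2000), {1900: 300.0, 2000: 400.0})


class TestClimateGenerator:
    def test_empty_locations_rejected(self):
        with pytest.raises(ValueError):
            fs.generate_climate([])

    def test_zero_trend_zero_noise_is_constant(self):
        spec = fs.ClimateTrendSpec(
            temp_delta={s: 0.0 for s in fs.SEASONS},
            prcp_delta={s: 0.0 for s in fs.SEASONS},
            temp_noise_sd=0.0, prcp_noise_sd=0.0,
            baseline_t_sd=0.0, baseline_p_sd=0.0,
        )
        clim = fs.generate_climate(["a"], (1990, 2000), spec, seed=1)
        for s in fs.SEASONS:
            sub = clim[clim["season"] == s]
            assert sub["tmean_c"].nunique() == 1
            assert sub["prcp_mm"].nunique() == 1

    def test_fixed_seed_reproducible(self):
        a = fs.generate_climate(["a", "b"], (1950, 2000), seed=9)
        b = fs.generate_climate(["a", "b"], (1950, 2000), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_default_winter_trends_match_configured_shifts(self):
        """Fitted 1960->2023 winter changes average +0.7 degC and +15.4 mm."""
        locs = [f"L{i}" for i in range(400)]
        clim = fs.generate_climate(locs, (1960, 2023), seed=11)
        sub = clim[clim["season"] == "winter"]
        years = np.arange(1960, 2024)
        dt, dp = [], []
        for _, grp in sub.groupby("location"):
            g = grp.sort_values("year")
            st = np.polyfit(years, g["tmean_c"], 1)[0]
            sp = np.polyfit(years, g["prcp_mm"], 1)[0]
            dt.append(st * 63)
            dp.append(sp * 63)
        assert np.mean(dt) == pytest.approx(0.7, abs=0.1)
        assert np.mean(dp) == pytest.approx(15.4, abs=3.5)


class TestPlotGenerator:
    def test_zero_noise_volume_equals_hand_formula(self, climate_small, co2_default):
        """With no noise, log volume is exactly the yield formula."""
        tp0 = fs.TrueParams.default(noise_sd=0.0)
        plots = fs.generate_plots(tp0, climate_small, co2_default,
                                  n_per_group=3, planted_fraction=0.5, seed=7)
        cidx, xidx = fs.ClimateIndex(climate_small), fs.CO2Index(co2_default)
        for _, row in plots.iterrows():
            expo = fs.lifetime_exposure(row["location"], int(row["age"]),
                                        int(row["year"]), cidx, xidx)
            gp = tp0.groups[row["group"]]
            lp = gp.intercept - gp.theta / row["age"] + tp0.gamma * np.log(expo.co2)
            for s in fs.SEASONS:
                t = (expo.tmean[s] - tp0.t_centers[s]) / T_SCALE
                p = (expo.prcp[s] - tp0.p_centers[s]) / P_SCALE
                for k in (1, 2, 3):
                    lp += tp0.temp_coefs[s][k - 1] * t**k
                    lp += tp0.prcp_coefs[s][k - 1] * p**k
            expected = np.exp(lp) + (tp0.premium(row["group"], row["age"])
                                     if row["origin"] == "planted" else 0.0)
            assert row["volume_m3ha"] == pytest.approx(expected, rel=1e-10)

    def test_zero_premium_schedule_leaves_planted_volumes_unchanged(
            self, climate_small, co2_default):
        tp = fs.TrueParams.default(noise_sd=0.0)
        zero_knots = tuple((a, 0.0) for a in (10, 20, 30, 40, 50))
        groups = {g: fs.GroupParams(gp.intercept, gp.theta,
                                    zero_knots if gp.premium_knots else ())
                  for g, gp in tp.groups.items()}
        tp0 = fs.TrueParams(groups=groups, temp_coefs=tp.temp_coefs,
                            prcp_coefs=tp.prcp_coefs, gamma=tp.gamma, noise_sd=0.0)
        plots = fs.generate_plots(tp0, climate_small, co2_default,
                                  n_per_group=40, planted_fraction=0.5, seed=8)
        planted = plots[plots["origin"] == "planted"]
        assert len(planted) > 0
        truth = tp0.to_results()
        cidx, xidx = fs.ClimateIndex(climate_small), fs.CO2Index(co2_default)
        for _, row in planted.iterrows():
            expo = fs.lifetime_exposure(row["location"], int(row["age"]),
                                        int(row["year"]), cidx, xidx)
            v_nat = truth.predict_volume(expo, group=row["group"])
            assert row["volume_m3ha"] == pytest.approx(v_nat, rel=1e-10)

    def test_log_residual_mean_near_zero_at_large_n(self, co2_default):
        """Law of large numbers: mean log-volume residual ~ 0 within 3 SD/sqrt(n)."""
        tp = fs.TrueParams.default()
        clim = fs.generate_climate([f"c{i:02d}" for i in range(10)], seed=21)
        plots = fs.generate_plots(tp, clim, co2_default, n_per_group=1000, seed=22)
        natural = plots[plots["origin"] == "natural"]
        expo = fs.exposure_table(natural, clim, co2_default)
        from forestsink.synthetic import _linear_predictor_vec
        lp = _linear_predictor_vec(tp.to_results(), natural, expo)
        resid = np.log(natural["volume_m3ha"].to_numpy()) - lp
        n = len(resid)
        assert abs(resid.mean()) < 3 * tp.noise_sd / np.sqrt(n)

    def test_age_outside_coverage_raises(self, co2_default):
        clim = fs.generate_climate(["a"], (1950, 2023), seed=1)
        tp = fs.TrueParams.default()
        with pytest.raises(ValueError):
            fs.generate_plots(tp, clim, co2_default, n_per_group=50,
                              age_range=(150, 150), seed=1)


class TestInventoryGenerator:
    def test_overlapping_age_classes_rejected(self, true_params, climate_small, co2_default):
        region = fs.RegionSpec(age_classes=((1, 10), (5, 20)))
        with pytest.raises(ValueError, match="overlap"):
            fs.generate_inventory(true_params, region, climate_small, co2_default)

    def test_observed_volume_is_area_weighted_yield_plus_shock(
            self, climate_small, co2_default):
        """Conservation: observed = sum(area x expected yield) + injected shock."""
        tp = fs.TrueParams.default(noise_sd=0.0)
        region = fs.RegionSpec(location="c00")
        shock = 3.3e7
        inv1, inv2 = fs.generate_inventory(tp, region, climate_small, co2_default,
                                           census_years=(2005, 2022), seed=5,
                                           shock=shock)
        truth = tp.to_results()
        cidx, xidx = fs.ClimateIndex(climate_small), fs.CO2Index(co2_default)
        for inv, add in ((inv1, 0.0), (inv2, shock)):
            total = 0.0
            for row in inv.areas.itertuples(index=False):
                age = fs.midpoint_age(row.age_lo, row.age_hi)
                expo = fs.mixed_exposure("c00", age, cidx, xidx,
                                         inv.year, inv.year, inv.year)
                y = truth.predict_volume(expo, age=age, group=row.group)
                if row.origin == "planted":
                    y += tp.premium(row.group, age)
                total += row.area_ha * y
            assert inv.total_observed_volume == pytest.approx(total + add, rel=1e-10)

    def test_scaling_areas_scales_observed_volume(self, climate_small, co2_default):
        tp = fs.TrueParams.default(noise_sd=0.0)
        region = fs.RegionSpec(location="c00", groups=("Oak/Hickory",))
        inv1, _ = fs.generate_inventory(tp, region, climate_small, co2_default, seed=6)
        doubled = inv1.areas.copy()
        doubled["area_ha"] *= 2.0
        truth = tp.to_results()
        v1 = fs.aggregate_volume(truth, inv1.areas, climate_small, co2_default,
                                 location="c00", temp_year=inv1.year,
                                 precip_year=inv1.year, co2_year=inv1.year)
        v2 = fs.aggregate_volume(truth, doubled, climate_small, co2_default,
                                 location="c00", temp_year=inv1.year,
                                 precip_year=inv1.year, co2_year=inv1.year)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)
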