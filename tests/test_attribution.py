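"""Telescoping attribution: additivity, oracles, residual closure, order effects."""

import numpy as np
import pandas as pd
import pytest

import forestsink as fs
from forestsink.experiments import _brute_force_contributions

LOC = "c00"


@pytest.fixture(scope="module")
def toy(climate_small, co2_default):
    """Two-group toy census pair with a known shock, plus the true model."""
    tp = fs.TrueParams.default(noise_sd=0.0)
    region = fs.RegionSpec(location=LOC,
                           groups=("Loblolly/Shortleaf Pine", "Oak/Hickory"))
    shock = -4.2e7
    inv1, inv2 = fs.generate_inventory(tp, region, climate_small, co2_default,
                                       census_years=(2005, 2022), seed=17,
                                       shock=shock)
    return tp, tp.to_results(), inv1, inv2, shock


class TestInventoryTable:
    def test_negative_area_rejected(self):
        areas = pd.DataFrame({"group": ["g"], "age_lo": [1], "age_hi": [10],
                              "origin": ["natural"], "area_ha": [-1.0]})
        obs = pd.DataFrame({"group": ["g"], "volume_m3": [0.0]})
        with pytest.raises(ValueError, match="negative"):
            fs.InventoryTable("R", 2000, areas, obs)

    def test_overlapping_age_classes_rejected(self):
        areas = pd.DataFrame({"group": ["g", "g"], "age_lo": [1, 8],
                              "age_hi": [10, 20], "origin": ["natural"] * 2,
                              "area_ha": [1.0, 1.0]})
        obs = pd.DataFrame({"group": ["g"], "volume_m3": [0.0]})
        with pytest.raises(ValueError, match="overlap"):
            fs.InventoryTable("R", 2000, areas, obs)

    @pytest.mark.parametrize("lo, hi, mid", [(1, 10, 6), (91, 100, 96), (5, 5, 5)])
    def test_midpoint_age_rounds_half_up(self, lo, hi, mid):
        assert fs.midpoint_age(lo, hi) == mid


class TestAggregateVolume:
    def test_zero_areas_give_zero_stock(self, toy, climate_small, co2_default):
        _, truth, inv1, _, _ = toy
        empty = inv1.areas.copy()
        empty["area_ha"] = 0.0
        v = fs.aggregate_volume(truth, empty, climate_small, co2_default,
                                location=LOC, temp_year=2005, precip_year=2005,
                                co2_year=2005)
        assert v == 0.0

    def test_single_cell_equals_area_times_yield(self, toy, climate_small, co2_default):
        tp, truth, *_ = toy
        areas = pd.DataFrame({"group": ["Oak/Hickory"], "age_lo": [21],
                              "age_hi": [30], "origin": ["natural"],
                              "area_ha": [1234.0]})
        v = fs.aggregate_volume(truth, areas, climate_small, co2_default,
                                location=LOC, temp_year=2005, precip_year=2005,
                                co2_year=2005)
        cidx, xidx = fs.ClimateIndex(climate_small), fs.CO2Index(co2_default)
        expo = fs.mixed_exposure(LOC, 26, cidx, xidx, 2005, 2005, 2005)
        assert v == pytest.approx(1234.0 * truth.predict_volume(expo, age=26,
                                                                group="Oak/Hickory"),
                                  rel=1e-12)

    def test_planting_flag_adds_premium_pool(self, toy, climate_small, co2_default):
        tp, truth, inv1, _, _ = toy
        common = dict(location=LOC, temp_year=2005, precip_year=2005, co2_year=2005)
        v_off = fs.aggregate_volume(truth, inv1.areas, climate_small, co2_default,
                                    **common)
        v_on = fs.aggregate_volume(truth, inv1.areas, climate_small, co2_default,
                                   planting=True, premium=tp.premium, **common)
        from forestsink.attribution import premium_pool
        assert v_on - v_off == pytest.approx(premium_pool(inv1.areas, tp.premium),
                                             rel=1e-12)


class TestDecompose:
    def test_identical_censuses_give_all_zero_contributions(
            self, toy, climate_small, co2_default):
        tp, truth, inv1, _, _ = toy
        twin = fs.InventoryTable(inv1.region, inv1.year, inv1.areas.copy(),
                                 inv1.observed_volume.copy())
        res = fs.decompose(truth, inv1, twin, climate_small, co2_default,
                           tp.premium, location=LOC)
        for d, c in res.contributions.items():
            assert c == pytest.approx(0.0, abs=1e-9), d
        assert res.unexplained == pytest.approx(0.0, abs=1e-9)

    def test_contributions_match_brute_force_sequence(self, toy, climate_small,
                                                      co2_default):
        """Each contribution equals the corresponding direct stock difference."""
        tp, truth, inv1, inv2, _ = toy
        res = fs.decompose(truth, inv1, inv2, climate_small, co2_default,
                           tp.premium, location=LOC)
        cidx, xidx = fs.ClimateIndex(climate_small), fs.CO2Index(co2_default)
        oracle = _brute_force_contributions(truth, inv1, inv2, cidx, xidx,
                                            tp.premium, LOC, fs.DRIVERS)
        for d in fs.DRIVERS:
            assert res.contributions[d] * 1e6 == pytest.approx(oracle[d], rel=1e-9), d

    def test_unexplained_equals_injected_shock(self, toy, climate_small, co2_default):
        tp, truth, inv1, inv2, shock = toy
        res = fs.decompose(truth, inv1, inv2, climate_small, co2_default,
                           tp.premium, location=LOC)
        assert res.unexplained * 1e6 == pytest.approx(shock, rel=1e-9)

    def test_contributions_sum_to_explained_and_residual_closes(
            self, toy, climate_small, co2_default):
        tp, truth, inv1, inv2, _ = toy
        res = fs.decompose(truth, inv1, inv2, climate_small, co2_default,
                           tp.premium, location=LOC)
        assert sum(res.contributions.values()) == pytest.approx(res.explained,
                                                                rel=1e-12)
        assert res.explained + res.unexplained == pytest.approx(res.observed_change,
                                                                rel=1e-12)

    def test_null_driver_contributes_zero_in_any_order(self, toy, climate_small,
                                                       co2_default):
        """A driver whose start and end states coincide contributes exactly 0."""
        tp, truth, inv1, inv2, _ = toy
        same_areas = fs.InventoryTable(inv2.region, inv2.year, inv1.areas.copy(),
                                       inv2.observed_volume.copy())
        for order in (fs.DRIVERS, tuple(reversed(fs.DRIVERS))):
            res = fs.decompose(truth, inv1, same_areas, climate_small, co2_default,
                               tp.premium, location=LOC, order=order)
            assert res.contributions["area"] == pytest.approx(0.0, abs=1e-9)
            assert res.contributions["age"] == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_group_structure_rejected(self, toy, climate_small, co2_default):
        tp, truth, inv1, inv2, _ = toy
        chopped = fs.InventoryTable(
            inv2.region, inv2.year,
            inv2.areas[inv2.areas["group"] == "Oak/Hickory"].copy(),
            inv2.observed_volume.copy())
        with pytest.raises(ValueError, match="group structure"):
            fs.decompose(truth, inv1, chopped, climate_small, co2_default,
                         tp.premium, location=LOC)


class TestReorderSensitivity:
    def test_ranges_match_brute_force_over_sample_of_orders(self, toy, climate_small,
                                                            co2_default):
        import itertools
        tp, truth, inv1, inv2, _ = toy
        perms = list(itertools.permutations(fs.DRIVERS))[:24]
        rs = fs.reorder_sensitivity(truth, inv1, inv2, climate_small, co2_default,
                                    tp.premium, location=LOC, permutations=perms)
        cidx, xidx = fs.ClimateIndex(climate_small), fs.CO2Index(co2_default)
        cache = {}
        bf = {d: [] for d in fs.DRIVERS}
        for perm in perms:
            c = _brute_force_contributions(truth, inv1, inv2, cidx, xidx,
                                           tp.premium, LOC, perm, cache=cache)
            for d in fs.DRIVERS:
                bf[d].append(c[d] / 1e6)
        for i, d in enumerate(fs.DRIVERS):
            assert rs["min_million_m3"][i] == pytest.approx(min(bf[d]), rel=1e-9)
            assert rs["max_million_m3"][i] == pytest.approx(max(bf[d]), rel=1e-9)

    def test_explained_total_invariant_to_order(self, toy, climate_small, co2_default):
        tp, truth, inv1, inv2, _ = toy
        rs = fs.reorder_sensitivity(truth, inv1, inv2, climate_small, co2_default,
                                    tp.premium, location=LOC)
        assert rs.attrs["explained_range_m3"] == pytest.approx(0.0, abs=1.0)

    def test_planting_contribution_is_order_invariant(self, toy, climate_small,
                                                      co2_default):
        """The premium pool acts on a disjoint term, so its range collapses."""
        tp, truth, inv1, inv2, _ = toy
        rs = fs.reorder_sensitivity(truth, inv1, inv2, climate_small, co2_default,
                                    tp.premium, location=LOC)
        row = rs[rs["driver"] == "planting"].iloc[0]
        assert row["max_million_m3"] - row["min_million_m3"] == pytest.approx(0.0,
                                                                             abs=1e-9)

    def test_too_many_permutations_rejected(self, toy, climate_small, co2_default):
        tp, truth, inv1, inv2, _ = toy
        perms = [fs.DRIVERS] * 721
        with pytest.raises(ValueError, match="720"):
            fs.reorder_sensitivity(truth, inv1, inv2, climate_small, co2_default,
                                   tp.premium, location=LOC, permutations=perms)
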