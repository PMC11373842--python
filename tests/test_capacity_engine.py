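import dataclasses
import math

import pandas as pd
import pytest

from foodprint import (
    FoodGroupVector,
    GrazingAdjustment,
    LandBase,
    ScenarioConfig,
    amendment_use,
    grazing_adjustment,
    land_availability,
    nutrient_summary,
    population_fed,
    run_single,
    total_land_use,
)
from foodprint.capacity_engine import LandAvailability
from foodprint.errors import PipelineError
from foodprint.land_engine import LandResult


def _land_result(cultivated=0.0, forage=0.0, grazing=0.0):
    rows = []
    if cultivated:
        rows.append(("f1", "wheat", "cultivated_cropland", cultivated))
    if forage:
        rows.append(("f2", "hay", "cropland_pasture", forage))
    if grazing:
        rows.append(("f3", "grazed_forage", "permanent_pasture", grazing))
    return LandResult(
        table=pd.DataFrame(
            rows, columns=["food_id", "commodity_id", "land_type", "acres"]
        )
    )


def _avail(ci=1.0, cult=100.0, all_uses=200.0, grazing=400.0):
    return LandAvailability(
        cropping_intensity=ci,
        productive_cropland=all_uses,
        proportion_cultivated=1.0,
        available_cultivated_food_cropland=cult,
        available_grazing_land=grazing,
        available_food_cropland_all_uses=all_uses,
    )


class TestLandAvailability:
    def test_cropping_intensity_division(self):
        base = LandBase(120, 100, 150, 50, 120, 10, 800, 200)
        avail = land_availability(base)
        assert avail.cropping_intensity == pytest.approx(1.2)
        assert avail.productive_cropland == pytest.approx(200)
        assert avail.proportion_cultivated == pytest.approx(0.6)
        assert avail.available_cultivated_food_cropland == pytest.approx(90)
        assert avail.available_food_cropland_all_uses == pytest.approx(190)

    def test_grazing_sum(self):
        base = LandBase(120, 100, 150, 50, 120, 10, 80, 20)
        assert land_availability(base).available_grazing_land == pytest.approx(100)

    def test_nonfood_exceeding_cultivated_floored(self, caplog):
        base = LandBase(120, 100, 150, 50, 120, 1e6, 80, 20)
        with caplog.at_level("WARNING"):
            avail = land_availability(base)
        assert avail.available_cultivated_food_cropland == 0.0
        assert "floored" in caplog.text

    def test_zero_cultivated_area_fatal(self):
        base = LandBase(120, 0, 150, 50, 120, 10, 80, 20)
        with pytest.raises(PipelineError, match="total_area_cultivated"):
            land_availability(base)


class TestGrazingAdjustment:
    def _params_with_ry(self, mini_params, ry):
        # RY = cropland grazing yield / grazing-land yield
        yields = mini_params.yields.copy()
        mask_p = (yields["commodity_id"] == "grazed_forage") & (
            yields["land_type"] == "cropland_pasture"
        )
        mask_g = (yields["commodity_id"] == "grazed_forage") & (
            yields["land_type"] == "permanent_pasture"
        )
        yields.loc[mask_g, "yield_lb_per_acre"] = 4000.0
        yields.loc[mask_p, "yield_lb_per_acre"] = 4000.0 * ry
        return dataclasses.replace(mini_params, yields=yields)

    def test_rr_below_ra_no_reallocation(self, mini_params):
        params = self._params_with_ry(mini_params, 0.5)
        land = _land_result(cultivated=20.0, grazing=30.0)
        adj = grazing_adjustment(land, _avail(ci=1.0), params)
        assert adj.ra == pytest.approx(2.0)
        assert adj.rr == pytest.approx(1.5)
        assert adj.cropland_used_for_grazing == 0.0
        assert adj.grazing_land_offset == 0.0

    def test_piecewise_example(self, mini_params):
        # RA=2, RY=0.5, grazing 120, crop side 20 -> (120-40)/2.5 = 32; offset 16
        params = self._params_with_ry(mini_params, 0.5)
        land = _land_result(cultivated=20.0, grazing=120.0)
        adj = grazing_adjustment(land, _avail(ci=1.0), params)
        assert adj.ry == pytest.approx(0.5)
        assert adj.cropland_used_for_grazing == pytest.approx(32.0)
        assert adj.grazing_land_offset == pytest.approx(16.0)

    def test_zero_grazing_demand(self, mini_params):
        land = _land_result(cultivated=20.0)
        adj = grazing_adjustment(land, _avail(), mini_params)
        assert adj.rr == 0.0
        assert adj.cropland_used_for_grazing == 0.0

    def test_offset_invariant(self, mini_params):
        land = _land_result(cultivated=5.0, forage=2.0, grazing=500.0)
        adj = grazing_adjustment(land, _avail(), mini_params)
        assert adj.grazing_land_offset == pytest.approx(
            adj.cropland_used_for_grazing * adj.ry
        )

    def test_forage_mass_balance(self, mini_params):
        # forage from reallocated cropland (acres x cropland yield) equals
        # the pasture supply it replaces (offset x grazing-land yield)
        land = _land_result(cultivated=5.0, forage=2.0, grazing=500.0)
        adj = grazing_adjustment(land, _avail(), mini_params)
        assert adj.cropland_used_for_grazing > 0
        yield_p = mini_params.yield_for("grazed_forage", "cropland_pasture")
        yield_g = mini_params.yield_for("grazed_forage", "permanent_pasture")
        assert adj.cropland_used_for_grazing * yield_p == pytest.approx(
            adj.grazing_land_offset * yield_g, rel=1e-9
        )

    def test_post_adjustment_ratio_equals_ra(self, mini_params):
        land = _land_result(cultivated=5.0, forage=2.0, grazing=500.0)
        avail = _avail()
        adj = grazing_adjustment(land, avail, mini_params)
        post_grazing = land.total("permanent_pasture") - adj.grazing_land_offset
        post_crop = (
            land.total("cultivated_cropland") / avail.cropping_intensity
            + land.total("cropland_pasture")
            + adj.cropland_used_for_grazing
        )
        assert post_grazing / post_crop == pytest.approx(adj.ra, rel=1e-9)

    def test_remaining_pasture_nonnegative(self, mini_params):
        land = _land_result(cultivated=0.1, forage=0.05, grazing=900.0)
        adj = grazing_adjustment(land, _avail(), mini_params)
        assert (
            land.total("permanent_pasture") - adj.grazing_land_offset >= -1e-12
        )


class TestPopulationFed:
    def test_min_over_three(self):
        land = _land_result(cultivated=1.0, grazing=1.0)
        avail = _avail(ci=1.0, cult=90.0, all_uses=120.0, grazing=80.0)
        adj = GrazingAdjustment(1.0, 0.0, 1.0, 0.0, 0.0)
        pf = population_fed(land, avail, adj, population=200.0)
        assert pf.cultivated_cropland == pytest.approx(90.0)
        assert pf.all_cropland == pytest.approx(120.0)
        assert pf.all_productive_land == pytest.approx(100.0)
        assert pf.carrying_capacity == pytest.approx(0.45)

    def test_carrying_capacity_invariant(self, reference_result):
        pf = reference_result.population_fed
        assert pf.carrying_capacity == pytest.approx(
            pf.minimum() / reference_result.population
        )

    def test_no_grazing_reduces_third_to_second_plus_terms(self):
        # with no grazing demand and no reallocation, the third formula is
        # the second with extra availability only
        land = _land_result(cultivated=2.0, forage=1.0)
        avail = _avail(ci=2.0)
        adj = GrazingAdjustment(1.0, 0.0, 1.0, 0.0, 0.0)
        pf = population_fed(land, avail, adj, population=10.0)
        denom = 2.0 / 2.0 + 1.0
        assert pf.all_cropland == pytest.approx(
            avail.available_food_cropland_all_uses / denom
        )
        assert pf.all_productive_land == pytest.approx(
            (avail.available_food_cropland_all_uses + avail.available_grazing_land)
            / denom
        )

    def test_zero_requirement_unbounded(self):
        land = _land_result()
        avail = _avail()
        adj = GrazingAdjustment(1.0, 0.0, 1.0, 0.0, 0.0)
        pf = population_fed(land, avail, adj, population=10.0)
        assert math.isinf(pf.cultivated_cropland)
        assert math.isinf(pf.carrying_capacity)

    def test_open_trade_warning(self):
        land = _land_result(cultivated=1.0)
        pf = population_fed(
            land, _avail(), GrazingAdjustment(1, 0, 1, 0, 0), 10.0,
            trade_mode="open",
        )
        assert pf.warning is not None


class TestTotalLandUse:
    def test_zero_adjustment_reduction(self):
        land = _land_result(cultivated=12.0, forage=3.0, grazing=5.0)
        adj = GrazingAdjustment(1.0, 0.0, 1.0, 0.0, 0.0)
        total = total_land_use(land, adj, cropping_intensity=1.2, population=10.0)
        assert total == pytest.approx((12.0 / 1.2 + 3.0 + 5.0) * 10.0)

    def test_reallocation_arithmetic(self):
        land = _land_result(cultivated=12.0, forage=3.0, grazing=100.0)
        adj = GrazingAdjustment(2.0, 5.0, 0.5, 32.0, 16.0)
        total = total_land_use(land, adj, 1.0, 1.0)
        assert total == pytest.approx(12.0 + (3.0 + 32.0) + (100.0 - 16.0))

    def test_population_linearity(self):
        land = _land_result(cultivated=12.0, forage=3.0, grazing=5.0)
        adj = GrazingAdjustment(1.0, 0.0, 1.0, 0.0, 0.0)
        t1 = total_land_use(land, adj, 1.2, 10.0)
        t2 = total_land_use(land, adj, 1.2, 20.0)
        assert t2 == pytest.approx(2 * t1)


class TestAmendmentUse:
    def test_simple_sum(self):
        land = LandResult(
            table=pd.DataFrame(
                [
                    ("a", "wheat", "cultivated_cropland", 2.0),
                    ("b", "hay", "cropland_pasture", 3.0),
                ],
                columns=["food_id", "commodity_id", "land_type", "acres"],
            )
        )
        rates = pd.DataFrame(
            [("wheat", "N", 10.0), ("hay", "N", 0.0)],
            columns=["commodity_id", "amendment", "rate"],
        )
        totals, breakdown = amendment_use(land, rates)
        assert totals["N"] == pytest.approx(20.0)
        assert totals["pesticides"] == 0.0

    def test_zero_land_zero_amendments(self):
        land = _land_result()
        rates = pd.DataFrame(
            [("wheat", "N", 10.0)], columns=["commodity_id", "amendment", "rate"]
        )
        totals, _ = amendment_use(land, rates)
        assert all(v == 0.0 for v in totals.values())

    def test_missing_rate_warns_and_contributes_zero(self, caplog):
        land = _land_result(cultivated=2.0)
        rates = pd.DataFrame(
            [("corn", "N", 10.0)], columns=["commodity_id", "amendment", "rate"]
        )
        with caplog.at_level("WARNING"):
            totals, _ = amendment_use(land, rates)
        assert totals["N"] == 0.0
        assert "conservative" in caplog.text

    def test_negative_rate_fatal(self):
        land = _land_result(cultivated=2.0)
        rates = pd.DataFrame(
            [("wheat", "N", -1.0)], columns=["commodity_id", "amendment", "rate"]
        )
        with pytest.raises(PipelineError, match="negative amendment rate"):
            amendment_use(land, rates)

    def test_brute_force_grid(self, reference_result, mini_params):
        # brute-force: sum acres x rate over the full food x amendment grid
        rate_map = {
            (r["commodity_id"], r["amendment"]): r["rate"]
            for _, r in mini_params.amendments.iterrows()
        }
        for amendment in ("N", "P2O5", "K2O", "S", "pesticides", "irrigation"):
            brute = sum(
                row["acres"] * rate_map.get((row["commodity_id"], amendment), 0.0)
                for _, row in reference_result.land.table.iterrows()
            )
            assert reference_result.amendments[amendment] == pytest.approx(
                brute, rel=1e-12, abs=1e-15
            )


class TestNutrientSummary:
    def test_single_food(self, mini_params):
        diet = FoodGroupVector({"fruit": 2.0})  # apple: 95 kcal/serving
        out = nutrient_summary(diet, mini_params)
        assert out["energy_kcal"] == pytest.approx(190.0)

    def test_zero_diet(self, mini_params):
        out = nutrient_summary(FoodGroupVector.zeros(), mini_params)
        assert all(v == 0.0 for v in out.values())

    def test_reference_diet_hand_sum(self, reference_result):
        # 160+50+130+95+150+170+210+100+60+120+36+60 = 1341
        assert reference_result.nutrients["energy_kcal"] == pytest.approx(1341.0)


class TestMeanVsIndividualDirection:
    def test_mean_of_individuals_below_mean_diet_when_triggered(
        self, mini_params
    ):
        # half the cohort has extreme beef intake that triggers RR > RA;
        # the mean diet does not trigger it
        scen = ScenarioConfig(population_size=100.0)
        low = FoodGroupVector({"grains": 2.0, "beef": 1.0, "fruit": 1.0})
        high = FoodGroupVector({"grains": 2.0, "beef": 40.0, "fruit": 1.0})
        mean = FoodGroupVector(
            {"grains": 2.0, "beef": 20.5, "fruit": 1.0}
        )
        res_low = run_single(low, mini_params, scen)
        res_high = run_single(high, mini_params, scen)
        res_mean = run_single(mean, mini_params, scen)
        assert res_high.grazing.rr > res_high.grazing.ra  # trigger
        mean_of_ind = 0.5 * (
            res_low.land_by_type["permanent_pasture"]
            + res_high.land_by_type["permanent_pasture"]
        )
        assert mean_of_ind < res_mean.land_by_type["permanent_pasture"]
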