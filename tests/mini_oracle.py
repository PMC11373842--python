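"""Independent hand-worksheet replication of the MINI reference run.

This module re-derives every intermediate of the MINI reference-diet
simulation with straight-line arithmetic and literal parameter values
(typed in from docs/mini_oracle.md) — it deliberately imports nothing
from the ``foodprint`` package so it can serve as an independent oracle.
"""

from types import SimpleNamespace


def compute_mini_oracle():
    """Return every intermediate of the MINI reference run as a namespace."""
    LB = 454.0
    YR = 365.0

    def annual(servings, grams, pref, lw, proc=1.0):
        return servings * grams / LB * pref * lw * proc * YR

    # ---- commodity masses, lb/person/yr (food requirements equation) ----
    # grains group: tortilla non-producible, so bread's raw 0.8 share
    # reapportions to 1.0
    bread_pref = 0.8 / 0.8
    wheat = annual(2.0, 28.0, bread_pref, 1.25, 1.37)  # 77.10
    carrot = annual(1.0, 120.0, 1.0, 1.50, 1.10)
    potato = annual(1.0, 160.0, 1.0, 1.60, 1.00)
    apple = annual(1.0, 150.0, 1.0, 1.40, 1.20)

    # dairy: per-food pre-processing masses, then limiting fraction
    milk_lb = annual(1.0, 245.0, 1.0, 1.10)
    cheese_lb = annual(1.0, 42.0, 1.0, 1.20)
    fm_fat = milk_lb * 0.037 / 0.037 + cheese_lb * 0.30 / 0.037
    fm_nonfat = milk_lb * 0.086 / 0.086 + cheese_lb * 0.25 / 0.086
    fm = max(fm_fat, fm_nonfat)  # fat-limited
    milk_fm_share = milk_lb * 0.037 / 0.037  # fat is limiting
    cheese_fm_share = cheese_lb * 0.30 / 0.037

    cattle = annual(3.0, 28.0, 1.0, 1.30, 1.50)
    broilers = annual(2.0, 28.0, 1.0, 1.25, 1.40)
    salmon_edible = annual(1.0, 28.0, 1.0, 1.20, 1.00)
    salmon_farmed = salmon_edible * 0.5
    salmon_wild = salmon_edible * 0.5
    oil_product = annual(3.0, 4.5, 1.0, 1.15, 1.00)
    soybean_oil = oil_product * 0.6
    corn_oil = oil_product * 0.4
    lard = annual(1.0, 4.0, 1.0, 1.10, 1.00)
    corn_sweetener = annual(4.0, 5.0, 1.0, 1.10, 1.60)

    # ---- aquaculture 2x2 (feed per edible = FCR / processing efficiency)
    feed_per_edible = 1.0 / 0.5
    e_req = feed_per_edible * 1.55  # 3.1
    p_req = feed_per_edible * 0.285  # 0.57
    # solve 1.6 c + 1.5 s = 3.1 ; 0.09 c + 0.48 s = 0.57 -> c = s = 1
    det = 1.6 * 0.48 - 1.5 * 0.09
    aqua_corn = (e_req * 0.48 - 1.5 * p_req) / det
    aqua_soymeal = (1.6 * p_req - e_req * 0.09) / det

    # ---- feed demands per food, lb/person/yr ----
    beef_forage = cattle * 6.0
    beef_corn = cattle * 2.0
    beef_hay = cattle * 1.0
    chicken_corn = broilers * 2.0
    chicken_soymeal = broilers * 1.0
    dairy_fm = fm  # fluid-milk commodity mass (processing conversion 1.0)
    dairy_hay = dairy_fm * 0.5
    dairy_forage = dairy_fm * 0.3
    dairy_corn = dairy_fm * 0.2
    salmon_corn = salmon_farmed * aqua_corn
    salmon_soymeal = salmon_farmed * aqua_soymeal

    # ---- multiuse ledger (8 steps) ----
    corn_oil_coproduced = corn_sweetener * 0.04  # step 1
    gluten_protein = corn_sweetener * 0.25 * 0.20  # step 1
    soy_for_oil = soybean_oil / 0.2  # step 2
    soy_meal_protein = soy_for_oil * 0.8 * 0.48  # step 3
    lard_coproduced = cattle * 0.04 + broilers * 0.02  # step 3
    corn_oil_spared = min(corn_oil, corn_oil_coproduced)  # step 4
    corn_spared = corn_oil_spared / 0.04  # step 4
    lard_remaining = max(0.0, lard - lard_coproduced)  # step 5
    surplus_fats = max(0.0, corn_oil_coproduced - corn_oil_spared) + max(
        0.0, lard_coproduced - lard
    )  # step 6
    displaced_oil = min(soybean_oil, surplus_fats)
    soy_spared_for_oil = displaced_oil / 0.2  # step 6 (lb soybeans)
    net_soy_crushed = soy_for_oil - soy_spared_for_oil  # step 7
    feed_protein = gluten_protein + net_soy_crushed * 0.8 * 0.48  # step 7
    soymeal_feed_demand = chicken_soymeal + salmon_soymeal  # step 8
    soymeal_displaced = min(soymeal_feed_demand, feed_protein / 0.48)
    soybean_spared_for_feed = soymeal_displaced / 0.8

    # ---- land, acres/person/yr ----
    land_wheat = wheat / 2700.0
    land_carrot = carrot / 30000.0
    land_potato = potato / 40000.0
    land_apple = apple / 25000.0
    corn_total = (
        corn_sweetener
        + beef_corn
        + chicken_corn
        + dairy_corn
        + salmon_corn
        + (corn_oil - corn_oil_spared) / 0.04
    )
    land_corn = corn_total / 9000.0
    soybeans_total = (
        (soybean_oil - displaced_oil) / 0.2
        + (soymeal_feed_demand - soymeal_displaced) / 0.8
    )
    land_soy = soybeans_total / 3000.0
    land_hay = (beef_hay + dairy_hay) / 5000.0
    land_grazing = (beef_forage + dairy_forage) / 2000.0

    cultivated = land_wheat + land_carrot + land_potato + land_apple + land_corn + land_soy
    forage = land_hay
    grazing = land_grazing

    # ---- availability / grazing adjustment / output ----
    ci = 120.0 / 100.0
    productive = 150.0 + 50.0
    prop_cult = 120.0 / productive
    avail_cult = productive * prop_cult / ci - 10.0  # 90
    avail_all = productive - 10.0  # 190
    avail_grazing = 800.0 + 200.0  # 1000

    ra = avail_grazing / avail_all
    # RY: cropland grazing yield over grazing-land yield (one cropland
    # acre of grazed forage frees RY acres of permanent pasture)
    ry = 4000.0 / 2000.0
    crop_side = cultivated / ci + forage
    rr = grazing / crop_side
    if rr > ra:
        cropland_grazing = (grazing - ra * crop_side) / (ra + ry)
    else:
        cropland_grazing = 0.0
    grazing_offset = cropland_grazing * ry

    population = 100.0
    pf_cult = avail_cult / cultivated
    pf_allcrop = avail_all / (cultivated / ci + forage + cropland_grazing)
    pf_allland = (avail_all + avail_grazing) / (
        cultivated / ci + forage + grazing + cropland_grazing - grazing_offset
    )
    carrying_capacity = min(pf_cult, pf_allcrop, pf_allland) / population
    total_land = (
        cultivated / ci + forage + cropland_grazing + grazing - grazing_offset
    ) * population

    # ---- amendments (per capita; apple has no rates -> 0) ----
    rates = {
        "wheat": (60.0, 30.0, 20.0, 5.0, 1.0, 0.5),
        "corn": (140.0, 60.0, 80.0, 10.0, 2.2, 0.8),
        "soybeans": (20.0, 40.0, 60.0, 5.0, 1.5, 0.4),
        "carrot": (100.0, 50.0, 70.0, 8.0, 3.0, 1.2),
        "potato": (180.0, 90.0, 120.0, 12.0, 4.0, 1.5),
        "hay": (40.0, 20.0, 30.0, 4.0, 0.5, 0.3),
        "apple": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        "grazed_forage": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    }
    acres = {
        "wheat": land_wheat,
        "corn": land_corn,
        "soybeans": land_soy,
        "carrot": land_carrot,
        "potato": land_potato,
        "hay": land_hay,
        "apple": land_apple,
        "grazed_forage": land_grazing,
    }
    amendments = {}
    for j, name in enumerate(("N", "P2O5", "K2O", "S", "pesticides", "irrigation")):
        amendments[name] = sum(acres[c] * rates[c][j] for c in acres)

    # ---- nutrient summary (per capita per day) ----
    nutrients = {}
    servings = {
        "bread": 2.0, "carrot": 1.0, "potato": 1.0, "apple": 1.0,
        "fluid_milk": 1.0, "cheese": 1.0, "beef": 3.0, "chicken": 2.0,
        "salmon": 1.0, "cooking_oil": 3.0, "lard": 1.0, "corn_syrup": 4.0,
    }
    comp = {
        "bread": (80.0, 3.0, 1.0, 15.0),
        "carrot": (50.0, 1.0, 0.2, 12.0),
        "potato": (130.0, 3.0, 0.2, 30.0),
        "apple": (95.0, 0.5, 0.3, 25.0),
        "fluid_milk": (150.0, 8.0, 8.0, 12.0),
        "cheese": (170.0, 10.0, 14.0, 1.0),
        "beef": (70.0, 7.0, 5.0, 0.0),
        "chicken": (50.0, 9.0, 2.0, 0.0),
        "salmon": (60.0, 8.0, 3.0, 0.0),
        "cooking_oil": (40.0, 0.0, 4.5, 0.0),
        "lard": (36.0, 0.0, 4.0, 0.0),
        "corn_syrup": (15.0, 0.0, 0.0, 4.0),
    }
    for j, key in enumerate(("energy_kcal", "protein_g", "fat_g", "carbohydrate_g")):
        nutrients[key] = sum(servings[f] * comp[f][j] for f in servings)

    return SimpleNamespace(**{k: v for k, v in locals().items() if k != "SimpleNamespace"})
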