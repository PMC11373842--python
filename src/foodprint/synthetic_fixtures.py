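"""Deterministic toy food system (MINI) and seeded synthetic diet surveys.

MINI is a 13-food system whose parameter values are chosen so every
pipeline mechanism is exercised by arithmetic a reviewer can redo on
paper: preference reapportionment (tortilla is non-producible), the
dairy limiting fraction (milk + cheese), livestock feed (beef, chicken,
dairy), the aquaculture corn/soymeal solve (farmed salmon, solving to
exactly 1 lb + 1 lb of feed per lb edible), the multiuse ledger (corn
sweetener, corn oil, soybean oil/meal, lard), and grazing reallocation.
The companion hand-computed oracle lives in docs/mini_oracle.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .diet_input import DietRecord, FoodGroupVector
from .food_system_data import (
    FoodSystemParameters,
    LandBase,
    validate_parameters,
    with_reapportioned_shares,
)

# ---------------------------------------------------------------------------
# MINI food system


def make_mini_food_system() -> FoodSystemParameters:
    """Build the deterministic MINI parameter set (validated)."""
    foods = pd.DataFrame(
        [
            # food_id, group, category, serving_g, unit, producible,
            # pref_raw, loss_waste, lw_legacy, processing, commodity
            ("bread", "grains", "grains", 28.0, "oz_eq", True, 0.8, 1.25, 1.50, 1.37, "wheat"),
            ("tortilla", "grains", "grains", 28.0, "oz_eq", False, 0.2, 1.20, 1.40, 1.30, "masa"),
            ("carrot", "other_vegetables", "vegetables", 120.0, "cup_eq", True, 1.0, 1.50, 1.80, 1.10, "carrot"),
            ("potato", "starchy_vegetables", "vegetables", 160.0, "cup_eq", True, 1.0, 1.60, 1.90, 1.00, "potato"),
            ("apple", "fruit", "fruit", 150.0, "cup_eq", True, 1.0, 1.40, 1.60, 1.20, "apple"),
            ("fluid_milk", "fluid_milk_yogurt", "dairy", 245.0, "cup_eq", True, 1.0, 1.10, 1.30, 1.00, "fluid_milk"),
            ("cheese", "cheese_other_dairy", "dairy", 42.0, "cup_eq", True, 1.0, 1.20, 1.40, 1.00, "fluid_milk"),
            ("beef", "beef", "beef", 28.0, "oz_eq", True, 1.0, 1.30, 1.70, 1.50, "cattle"),
            ("chicken", "chicken", "chicken", 28.0, "oz_eq", True, 1.0, 1.25, 1.55, 1.40, "broilers"),
            ("salmon", "aquatic_food", "seafood", 28.0, "oz_eq", True, 1.0, 1.20, 1.40, 1.00, "salmon"),
            ("cooking_oil", "plant_oils", "oils", 4.5, "tsp", True, 1.0, 1.15, 1.35, 1.00, "mixed_oil"),
            ("lard", "lard_tallow", "animal_fats", 4.0, "tsp", True, 1.0, 1.10, 1.30, 1.00, "lard_tallow"),
            ("corn_syrup", "sweeteners", "sweeteners", 5.0, "tsp", True, 1.0, 1.10, 1.25, 1.60, "corn"),
        ],
        columns=[
            "food_id", "food_group", "category", "serving_size_g",
            "serving_unit", "producible", "preference_share_raw",
            "loss_waste_factor", "loss_waste_factor__legacy",
            "processing_conversion", "commodity_id",
        ],
    )
    foods["preference_share"] = foods["preference_share_raw"]

    dairy = pd.DataFrame(
        [("fluid_milk", 0.037, 0.086), ("cheese", 0.30, 0.25)],
        columns=["food_id", "fat_solids", "nonfat_solids"],
    )
    fats_oils = pd.DataFrame(
        [("cooking_oil", "soybean_oil", 0.6), ("cooking_oil", "corn_oil", 0.4)],
        columns=["product_id", "oil_id", "share"],
    )
    feed = pd.DataFrame(
        [
            ("cattle", "grazed_forage", 6.0),
            ("cattle", "corn", 2.0),
            ("cattle", "hay", 1.0),
            ("broilers", "corn", 2.0),
            ("broilers", "soybean_meal", 1.0),
            ("fluid_milk", "hay", 0.5),
            ("fluid_milk", "grazed_forage", 0.3),
            ("fluid_milk", "corn", 0.2),
        ],
        columns=["animal_product_id", "feed_commodity_id", "lb_feed_per_lb_product"],
    )
    # fcr/eff = 2 lb feed per lb edible; energy 2*1.55 = 3.1, protein
    # 2*0.285 = 0.57, solving to exactly corn 1 lb + soymeal 1 lb
    aquaculture = pd.DataFrame(
        [("salmon", 0.5, 1.0, 0.5, 1.55, 0.285)],
        columns=[
            "species_id", "farmed_share", "fcr", "processing_efficiency",
            "ration_energy", "ration_protein",
        ],
    )
    feed_nutrients = pd.DataFrame(
        [("corn", 1.6, 0.09), ("soybean_meal", 1.5, 0.48)],
        columns=["feed_commodity_id", "energy_per_lb", "protein_per_lb"],
    )
    trade = pd.DataFrame(
        [(f, 0.0, 0.0, 0.0) for f in foods["food_id"]],
        columns=["food_id", "beginning_stock", "imports", "exports"],
    )
    yields = pd.DataFrame(
        [
            ("wheat", C.CULTIVATED, 2700.0),
            ("carrot", C.CULTIVATED, 30000.0),
            ("potato", C.CULTIVATED, 40000.0),
            ("apple", C.CULTIVATED, 25000.0),
            ("corn", C.CULTIVATED, 9000.0),
            ("soybeans", C.CULTIVATED, 3000.0),
            ("hay", C.CROPLAND_PASTURE, 5000.0),
            ("grazed_forage", C.PERMANENT_PASTURE, 2000.0),
            ("grazed_forage", C.CROPLAND_PASTURE, 4000.0),
        ],
        columns=["commodity_id", "land_type", "yield_lb_per_acre"],
    )
    amendment_rows = []
    base_rates = {
        # commodity: (N, P2O5, K2O, S, pesticides, irrigation acre-ft)
        "wheat": (60.0, 30.0, 20.0, 5.0, 1.0, 0.5),
        "corn": (140.0, 60.0, 80.0, 10.0, 2.2, 0.8),
        "soybeans": (20.0, 40.0, 60.0, 5.0, 1.5, 0.4),
        "carrot": (100.0, 50.0, 70.0, 8.0, 3.0, 1.2),
        "potato": (180.0, 90.0, 120.0, 12.0, 4.0, 1.5),
        "hay": (40.0, 20.0, 30.0, 4.0, 0.5, 0.3),
        # apple deliberately absent: exercises the missing-rate warning
        "grazed_forage": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    }
    for commodity, rates in base_rates.items():
        for amendment, rate in zip(C.AMENDMENTS, rates):
            amendment_rows.append((commodity, amendment, rate))
    amendments = pd.DataFrame(
        amendment_rows, columns=["commodity_id", "amendment", "rate"]
    )
    land_base = LandBase(
        area_harvested_field_veg_other=120.0,
        total_area_cultivated=100.0,
        cropland_harvested=150.0,
        cropland_pasture_grazing=50.0,
        total_cultivated_harvested_excl_forage=120.0,
        nonfood_cropland=10.0,
        permanent_pasture=800.0,
        woodland_grazed=200.0,
    )
    nutrients = pd.DataFrame(
        [
            ("bread", 80.0, 3.0, 1.0, 15.0),
            ("tortilla", 60.0, 2.0, 1.0, 12.0),
            ("carrot", 50.0, 1.0, 0.2, 12.0),
            ("potato", 130.0, 3.0, 0.2, 30.0),
            ("apple", 95.0, 0.5, 0.3, 25.0),
            ("fluid_milk", 150.0, 8.0, 8.0, 12.0),
            ("cheese", 170.0, 10.0, 14.0, 1.0),
            ("beef", 70.0, 7.0, 5.0, 0.0),
            ("chicken", 50.0, 9.0, 2.0, 0.0),
            ("salmon", 60.0, 8.0, 3.0, 0.0),
            ("cooking_oil", 40.0, 0.0, 4.5, 0.0),
            ("lard", 36.0, 0.0, 4.0, 0.0),
            ("corn_syrup", 15.0, 0.0, 0.0, 4.0),
        ],
        columns=["food_id", "energy_kcal", "protein_g", "fat_g", "carbohydrate_g"],
    )
    oilseeds = pd.DataFrame(
        [
            ("soybeans", "soybean_oil", 0.2, 0.8, 0.48),
            ("corn", "corn_oil", 0.04, 0.25, 0.20),
        ],
        columns=["oilseed_id", "oil_id", "oil_yield", "meal_yield", "meal_protein"],
    )
    fat_coproducts = pd.DataFrame(
        [("cattle", 0.04), ("broilers", 0.02)],
        columns=["animal_product_id", "lard_tallow_per_lb"],
    )

    params = FoodSystemParameters(
        foods=foods,
        dairy=dairy,
        fats_oils=fats_oils,
        feed=feed,
        aquaculture=aquaculture,
        feed_nutrients=feed_nutrients,
        trade=trade,
        yields=yields,
        amendments=amendments,
        land_base=land_base,
        nutrients=nutrients,
        oilseeds=oilseeds,
        fat_coproducts=fat_coproducts,
    )
    params = with_reapportioned_shares(params)
    problems = validate_parameters(params)
    if problems:  # pragma: no cover - fixture must always validate
        raise AssertionError(f"MINI fixture invalid: {problems}")
    return params


#: reference diet used by the MINI oracle worksheet (servings/day)
MINI_REFERENCE_DIET = {
    "grains": 2.0,
    "other_vegetables": 1.0,
    "starchy_vegetables": 1.0,
    "fruit": 1.0,
    "fluid_milk_yogurt": 1.0,
    "cheese_other_dairy": 1.0,
    "beef": 3.0,
    "chicken": 2.0,
    "aquatic_food": 1.0,
    "plant_oils": 3.0,
    "lard_tallow": 1.0,
    "sweeteners": 4.0,
}


def mini_reference_diet() -> FoodGroupVector:
    return FoodGroupVector(dict(MINI_REFERENCE_DIET))


# ---------------------------------------------------------------------------
# synthetic survey


@dataclass(frozen=True)
class FixtureSpec:
    """Controls for the seeded right-skewed synthetic diet survey.

    Per-group intakes are zero-inflated log-normal: with probability
    ``zero_prevalence[g]`` the intake is 0, otherwise
    exp(Normal(mu, sigma)) with (mu, sigma) = ``lognormal_params[g]``.
    A ``extreme_consumer_fraction`` of records get their beef intake
    multiplied by ``extreme_multiplier`` to push RR above RA on MINI.
    """

    seed: int = 0
    n_individuals: int = 100
    lognormal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            g: (np.log(max(v, 1e-9)), 0.5) for g, v in MINI_REFERENCE_DIET.items()
        }
    )
    zero_prevalence: dict[str, float] = field(
        default_factory=lambda: {g: 0.1 for g in MINI_REFERENCE_DIET}
    )
    extreme_consumer_fraction: float = 0.0
    extreme_multiplier: float = 12.0
    include_exclusion_triggers: bool = False

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for g, (mu, sigma) in self.lognormal_params.items():
            if not (np.isfinite(mu) and np.isfinite(sigma)):
                raise ValueError(f"non-finite log-normal parameters for {g!r}")

    def group_mean(self, group: str) -> float:
        """Expected intake of a group under the generator."""
        if group not in self.lognormal_params:
            return 0.0
        mu, sigma = self.lognormal_params[group]
        p0 = self.zero_prevalence.get(group, 0.0)
        return (1 - p0) * float(np.exp(mu + sigma**2 / 2))


def make_synthetic_survey(spec: FixtureSpec) -> list[DietRecord]:
    """Generate a seeded, reproducible synthetic diet survey.

    Records are drawn with a ``numpy.random.default_rng(seed)`` generator
    so output is bit-identical across runs and platforms.  When
    ``include_exclusion_triggers`` is set, three extra records are
    appended that trigger the age, reliability, and zero-intake
    exclusion rules respectively.
    """
    rng = np.random.default_rng(spec.seed)
    groups = C.FOOD_GROUPS
    records: list[DietRecord] = []
    n_extreme = int(round(spec.extreme_consumer_fraction * spec.n_individuals))
    for i in range(spec.n_individuals):
        intake = {}
        for g in groups:
            if g not in spec.lognormal_params:
                continue
            mu, sigma = spec.lognormal_params[g]
            p0 = spec.zero_prevalence.get(g, 0.0)
            if rng.random() < p0:
                intake[g] = 0.0
            else:
                intake[g] = float(rng.lognormal(mu, sigma))
        if i < n_extreme:
            intake["beef"] = intake.get("beef", 1.0) * spec.extreme_multiplier
            if intake["beef"] == 0.0:
                intake["beef"] = spec.extreme_multiplier
        records.append(
            DietRecord(
                participant_id=f"P{i:05d}",
                age_years=float(rng.integers(1, 85)),
                survey_weight=float(rng.uniform(0.5, 2.0)),
                survey_cycle="synthetic",
                recall_reliable=True,
                intake=FoodGroupVector(intake),
            )
        )
    if spec.include_exclusion_triggers:
        template = dict(MINI_REFERENCE_DIET)
        records.append(
            DietRecord("X_INFANT", 0.5, 1.0, FoodGroupVector(template))
        )
        records.append(
            DietRecord(
                "X_UNRELIABLE", 30.0, 1.0, FoodGroupVector(template),
                recall_reliable=False,
            )
        )
        records.append(
            DietRecord("X_ZERO", 30.0, 1.0, FoodGroupVector.zeros())
        )
    return records
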