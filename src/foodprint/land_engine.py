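"""Land requirements by land type, with the 8-step multiuse-crop ledger.

The multiuse ledger credits coproducts (corn oil and corn gluten feed
from sweetener milling, soybean meal and lard/tallow from oil crushing
and meat processing) so the same acres are not counted once per end use.
Spared quantities are commodity-mass offsets applied before division by
yield, and every intermediate is exposed for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import constants as C
from .commodity_flow import CommodityDemand
from .errors import PipelineError
from .food_system_data import FoodSystemParameters

log = logging.getLogger(__name__)


@dataclass
class MultiuseAdjustment:
    """Full coproduct ledger; all quantities in lb/person/yr.

    ``corn_spared`` offsets corn grown dedicatedly for corn oil,
    ``oilseed_spared`` offsets oilseeds grown for consumed oils, and
    ``soybean_spared`` offsets soybeans grown for feed meal.
    """

    corn_for_sweeteners: float = 0.0
    corn_gluten_feed_protein: float = 0.0  # step 1
    corn_oil_coproduced: float = 0.0  # step 1
    oil_demand: dict[str, float] = field(default_factory=dict)  # step 2
    seed_for_oil: dict[str, float] = field(default_factory=dict)  # step 2
    soybean_meal_protein_coproduced: float = 0.0  # step 3
    lard_tallow_coproduced: float = 0.0  # step 3
    corn_oil_consumed: float = 0.0  # step 4
    corn_oil_spared: float = 0.0  # step 4
    corn_spared: float = 0.0  # step 4, lb corn commodity
    lard_tallow_demand: float = 0.0  # step 5
    lard_tallow_remaining: float = 0.0  # step 5
    surplus_fats: float = 0.0  # step 6 input
    oilseed_spared: dict[str, float] = field(default_factory=dict)  # step 6
    feed_protein_coproduced: float = 0.0  # step 7
    soybean_meal_displaced: float = 0.0  # step 8
    soybean_spared: float = 0.0  # step 8, lb soybean commodity


def multiuse_adjustment(
    demand: CommodityDemand,
    feed: pd.DataFrame,
    params: FoodSystemParameters,
) -> MultiuseAdjustment:
    """Execute the coproduct ledger in order (steps 1-8).

    Degenerate inputs (no sweetener, oilseed, or animal-fat demand)
    produce all-zero adjustments; every spared quantity is floored at 0
    and corn-oil sparing is capped at min(consumed, coproduced).
    """
    adj = MultiuseAdjustment()
    oilseeds = params.oilseeds.set_index("oilseed_id", drop=False)
    oil_to_seed = {
        r["oil_id"]: r["oilseed_id"] for _, r in params.oilseeds.iterrows()
    }
    foods = params.foods.set_index("food_id")

    # step 1: corn gluten feed protein + corn oil coproduced from wet
    # milling whole corn for sweeteners
    sweetener_ids = set(
        params.foods[params.foods["food_group"] == "sweeteners"]["food_id"]
    )
    corn_sweet = demand.per_food[
        demand.per_food["food_id"].isin(sweetener_ids)
        & (demand.per_food["commodity_id"] == C.COMMODITY_CORN)
    ]
    adj.corn_for_sweeteners = float(corn_sweet["mass_lb"].sum())
    if C.COMMODITY_CORN in oilseeds.index:
        corn_row = oilseeds.loc[C.COMMODITY_CORN]
        adj.corn_oil_coproduced = adj.corn_for_sweeteners * float(
            corn_row["oil_yield"]
        )
        adj.corn_gluten_feed_protein = (
            adj.corn_for_sweeteners
            * float(corn_row["meal_yield"])
            * float(corn_row["meal_protein"])
        )

    # step 2: oil demand and dedicated seed requirement per oilseed oil
    if not demand.oils.empty:
        by_oil = demand.oils.groupby("oil_id")["mass_lb"].sum()
    else:
        by_oil = pd.Series(dtype=float)
    for oil_id, mass in by_oil.items():
        adj.oil_demand[oil_id] = float(mass)
        seed_id = oil_to_seed.get(oil_id)
        if seed_id is not None and seed_id != C.COMMODITY_CORN:
            oil_yield = float(oilseeds.loc[seed_id, "oil_yield"])
            if oil_yield > 0:
                adj.seed_for_oil[seed_id] = float(mass) / oil_yield

    # step 3: soybean meal protein from crushing, and lard/tallow
    # coproduced from animal-product processing
    soy_crushed = adj.seed_for_oil.get(C.COMMODITY_SOYBEANS, 0.0)
    if C.COMMODITY_SOYBEANS in oilseeds.index:
        soy_row = oilseeds.loc[C.COMMODITY_SOYBEANS]
        adj.soybean_meal_protein_coproduced = (
            soy_crushed * float(soy_row["meal_yield"]) * float(soy_row["meal_protein"])
        )
    fat_rates = dict(
        zip(
            params.fat_coproducts["animal_product_id"],
            params.fat_coproducts["lard_tallow_per_lb"].astype(float),
        )
    )
    for _, r in demand.per_food.iterrows():
        rate = fat_rates.get(r["commodity_id"])
        if rate:
            adj.lard_tallow_coproduced += float(r["mass_lb"]) * rate

    # step 4: corn spared via coproduced corn oil
    adj.corn_oil_consumed = float(by_oil.get(C.OIL_CORN, 0.0))
    adj.corn_oil_spared = min(adj.corn_oil_consumed, adj.corn_oil_coproduced)
    if C.COMMODITY_CORN in oilseeds.index:
        oil_yield = float(oilseeds.loc[C.COMMODITY_CORN, "oil_yield"])
        if oil_yield > 0:
            adj.corn_spared = adj.corn_oil_spared / oil_yield

    # step 5: lard/tallow remaining after coproduction credit
    lard_foods = demand.per_food[
        demand.per_food["commodity_id"] == C.COMMODITY_LARD_TALLOW
    ]
    adj.lard_tallow_demand = float(lard_foods["mass_lb"].sum())
    adj.lard_tallow_remaining = max(
        0.0, adj.lard_tallow_demand - adj.lard_tallow_coproduced
    )
    if adj.lard_tallow_remaining > 0:
        # remaining rendered fat is itself a coproduct of meat production
        # and is charged no dedicated land (conservative)
        log.warning(
            "lard/tallow demand exceeds coproduction by %.3f lb/person/yr; "
            "remainder carries no dedicated land",
            adj.lard_tallow_remaining,
        )

    # step 6: oilseeds spared via surplus corn oil and surplus lard/tallow
    surplus_corn_oil = max(0.0, adj.corn_oil_coproduced - adj.corn_oil_spared)
    surplus_fat = max(0.0, adj.lard_tallow_coproduced - adj.lard_tallow_demand)
    adj.surplus_fats = surplus_corn_oil + surplus_fat
    oilseed_oil_total = sum(
        m for o, m in adj.oil_demand.items()
        if oil_to_seed.get(o) not in (None, C.COMMODITY_CORN)
    )
    displaced_oil = min(oilseed_oil_total, adj.surplus_fats)
    if oilseed_oil_total > 0 and displaced_oil > 0:
        for oil_id, mass in adj.oil_demand.items():
            seed_id = oil_to_seed.get(oil_id)
            if seed_id in (None, C.COMMODITY_CORN):
                continue
            share = mass / oilseed_oil_total
            oil_yield = float(oilseeds.loc[seed_id, "oil_yield"])
            adj.oilseed_spared[seed_id] = (
                adj.oilseed_spared.get(seed_id, 0.0)
                + displaced_oil * share / oil_yield
            )

    # step 7: feed protein coproduced from the (net) oilseed crush plus
    # corn gluten feed from step 1
    adj.feed_protein_coproduced = adj.corn_gluten_feed_protein
    for seed_id, seed_mass in adj.seed_for_oil.items():
        net = max(0.0, seed_mass - adj.oilseed_spared.get(seed_id, 0.0))
        row = oilseeds.loc[seed_id]
        adj.feed_protein_coproduced += (
            net * float(row["meal_yield"]) * float(row["meal_protein"])
        )

    # step 8: soybeans spared via coproduced feed protein displacing
    # dedicated soybean-meal production
    if not feed.empty:
        soymeal_demand = float(
            feed[feed["feed_commodity_id"] == C.COMMODITY_SOYBEAN_MEAL][
                "mass_lb"
            ].sum()
        )
    else:
        soymeal_demand = 0.0
    if soymeal_demand > 0 and C.COMMODITY_SOYBEANS in oilseeds.index:
        soy_row = oilseeds.loc[C.COMMODITY_SOYBEANS]
        meal_protein = float(soy_row["meal_protein"])
        meal_yield = float(soy_row["meal_yield"])
        if meal_protein > 0 and meal_yield > 0:
            adj.soybean_meal_displaced = min(
                soymeal_demand, adj.feed_protein_coproduced / meal_protein
            )
            adj.soybean_spared = adj.soybean_meal_displaced / meal_yield
    return adj


@dataclass
class LandResult:
    """Per-food land requirement by land type (acres/person/yr)."""

    table: pd.DataFrame  # food_id, commodity_id, land_type, acres

    def total(self, land_type: str | None = None) -> float:
        df = self.table
        if land_type is not None:
            df = df[df["land_type"] == land_type]
        return float(df["acres"].sum())

    def by_land_type(self) -> pd.Series:
        out = self.table.groupby("land_type")["acres"].sum()
        return out.reindex(C.LAND_TYPES, fill_value=0.0)

    def by_food(self) -> pd.Series:
        return self.table.groupby("food_id")["acres"].sum()


def _prorate(total_spared: float, masses: list[float]) -> list[float]:
    total = sum(masses)
    if total <= 0 or total_spared <= 0:
        return [0.0] * len(masses)
    return [total_spared * m / total for m in masses]


def required_land(
    demand: CommodityDemand,
    feed: pd.DataFrame,
    adjustment: MultiuseAdjustment,
    params: FoodSystemParameters,
    trade_balances: pd.DataFrame | None = None,
    population: float = 1.0,
) -> LandResult:
    """Per-food, per-land-type acreage from commodity and feed demand.

    Trade balances, when given, are applied per capita before division by
    yield and floored so a surplus cannot create negative land.  Multiuse
    sparing is subtracted from the relevant commodity masses pro-rata
    across the foods that demand them.  Demand for a commodity with no
    yield row is fatal (silent drops would underestimate land), except
    for lard/tallow which is a pure coproduct.
    """
    if trade_balances is not None:
        from .feed_trade import apply_trade_balances

        demand = apply_trade_balances(demand, trade_balances, population)
        feed = feed  # feed must have been computed from adjusted demand

    oilseeds = params.oilseeds.set_index("oilseed_id", drop=False)
    oil_to_seed = {
        r["oil_id"]: r["oilseed_id"] for _, r in params.oilseeds.iterrows()
    }
    animal_products = set(params.feed["animal_product_id"])
    fat_foods = set(demand.oils["food_id"]) if not demand.oils.empty else set()

    mass_rows: list[dict] = []  # food_id, commodity_id, mass_lb

    # direct crop commodities (skip animal products -> via feed; skip fat
    # products -> via oils; skip lard/tallow -> pure coproduct)
    for _, r in demand.per_food.iterrows():
        commodity = r["commodity_id"]
        if commodity in animal_products:
            continue
        if r["food_id"] in fat_foods:
            continue
        if commodity == C.COMMODITY_LARD_TALLOW:
            continue
        mass_rows.append(
            {
                "food_id": r["food_id"],
                "commodity_id": commodity,
                "mass_lb": float(r["mass_lb"]),
            }
        )

    # sweetener corn: no offset here; corn sparing credits the dedicated
    # corn-for-oil demand below

    # feed commodities; soybean meal converts to whole soybeans with the
    # step-8 sparing applied pro-rata across the demanding foods
    if not feed.empty:
        soymeal = feed[feed["feed_commodity_id"] == C.COMMODITY_SOYBEAN_MEAL]
        other = feed[feed["feed_commodity_id"] != C.COMMODITY_SOYBEAN_MEAL]
        for _, r in other.iterrows():
            mass_rows.append(
                {
                    "food_id": r["food_id"],
                    "commodity_id": r["feed_commodity_id"],
                    "mass_lb": float(r["mass_lb"]),
                }
            )
        if not soymeal.empty:
            meal_yield = (
                float(oilseeds.loc[C.COMMODITY_SOYBEANS, "meal_yield"])
                if C.COMMODITY_SOYBEANS in oilseeds.index
                else 1.0
            )
            masses = [float(m) for m in soymeal["mass_lb"]]
            spared = _prorate(adjustment.soybean_meal_displaced, masses)
            for (_, r), sp in zip(soymeal.iterrows(), spared):
                net_meal = max(0.0, float(r["mass_lb"]) - sp)
                mass_rows.append(
                    {
                        "food_id": r["food_id"],
                        "commodity_id": C.COMMODITY_SOYBEANS,
                        "mass_lb": net_meal / meal_yield,
                    }
                )

    # oils: dedicated oilseed (or corn) production net of sparing
    if not demand.oils.empty:
        for oil_id, odf in demand.oils.groupby("oil_id"):
            seed_id = oil_to_seed.get(oil_id)
            if seed_id is None:
                raise PipelineError(
                    "land_engine", f"oil {oil_id!r} has no oilseed mapping"
                )
            oil_yield = float(oilseeds.loc[seed_id, "oil_yield"])
            if not oil_yield > 0:
                raise PipelineError(
                    "land_engine", f"oilseed {seed_id!r} has zero oil yield"
                )
            if seed_id == C.COMMODITY_CORN:
                spared_oil_total = adjustment.corn_oil_spared
            else:
                spared_oil_total = (
                    adjustment.oilseed_spared.get(seed_id, 0.0) * oil_yield
                )
            masses = [float(m) for m in odf["mass_lb"]]
            spared = _prorate(spared_oil_total, masses)
            for (_, r), sp in zip(odf.iterrows(), spared):
                net_oil = max(0.0, float(r["mass_lb"]) - sp)
                mass_rows.append(
                    {
                        "food_id": r["food_id"],
                        "commodity_id": seed_id,
                        "mass_lb": net_oil / oil_yield,
                    }
                )

    # divide by yield on the commodity's primary land type
    land_rows = []
    for row in mass_rows:
        mass = row["mass_lb"]
        if mass <= 0:
            continue
        commodity = row["commodity_id"]
        land_type = params.primary_land_type(commodity)
        if land_type is None:
            raise PipelineError(
                "land_engine",
                f"commodity {commodity!r} has positive demand but no yield row",
            )
        y = params.yield_for(commodity, land_type)
        if not y or y <= 0:
            raise PipelineError(
                "land_engine", f"zero yield for {commodity!r}/{land_type!r}"
            )
        land_rows.append(
            {
                "food_id": row["food_id"],
                "commodity_id": commodity,
                "land_type": land_type,
                "acres": mass / y,
            }
        )
    table = pd.DataFrame(
        land_rows, columns=["food_id", "commodity_id", "land_type", "acres"]
    )
    if not table.empty:
        table = (
            table.groupby(["food_id", "commodity_id", "land_type"], as_index=False)[
                "acres"
            ].sum()
        )
    return LandResult(table=table)
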