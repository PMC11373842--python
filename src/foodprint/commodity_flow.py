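"""Convert food-group servings into annual per-capita agricultural
commodity masses.

The chain per food is: group servings -> preference disaggregation ->
serving-size conversion to lb -> loss/waste inflation -> processing
conversion -> lb commodity per person per year.  Dairy foods are pooled
through the fluid-milk limiting-fraction computation, fat products are
decomposed into individual oils, and aquatic-food demand is split into a
farmed share (kept for agriculture) and a wild share (carried but
non-agricultural).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import constants as C
from .diet_input import FoodGroupVector
from .errors import PipelineError
from .food_system_data import FoodSystemParameters

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluidMilkResult:
    """Fluid-milk equivalents of a diet's dairy demand (lb/person/yr)."""

    fm_fat: float
    fm_nonfat: float
    fm: float
    limiting_fraction: str  # "fat" | "nonfat" | "none"
    #: per-food fluid-milk attribution by limiting-solids contribution
    per_food: dict[str, float] = field(default_factory=dict)


@dataclass
class CommodityDemand:
    """Per-food annual commodity masses plus routing detail.

    ``per_food`` has columns food_id, commodity_id, mass_lb (lb/person/yr);
    for animal foods the commodity is the animal product (feed conversion
    happens downstream), for fat products it is the composite product
    (decomposition detail lives in ``oils``), for dairy foods it is the
    attributed fluid-milk mass.
    """

    per_food: pd.DataFrame
    oils: pd.DataFrame  # food_id, oil_id, mass_lb
    dairy: FluidMilkResult
    farmed_fish: pd.DataFrame  # food_id, species_id, edible_lb
    wild_aquatic: pd.DataFrame  # food_id, edible_lb

    def per_commodity(self) -> pd.Series:
        if self.per_food.empty:
            return pd.Series(dtype=float)
        return self.per_food.groupby("commodity_id")["mass_lb"].sum()

    def food_mass(self, food_id: str) -> float:
        rows = self.per_food[self.per_food["food_id"] == food_id]
        return float(rows["mass_lb"].sum())


def reapportion_preferences(group_foods: pd.DataFrame) -> pd.Series:
    """Reapportion preference shares of non-producible foods.

    Non-producible foods get share 0; producible shares are renormalized
    proportionally to their raw shares so they sum to 1.

    Raises
    ------
    PipelineError
        If no food in the group is producible (group demand unservable).
    """
    raw = group_foods["preference_share_raw"].astype(float)
    producible = group_foods["producible"].astype(bool)
    if not producible.any():
        group = group_foods["food_group"].iloc[0] if len(group_foods) else "?"
        raise PipelineError(
            "commodity_flow", f"no producible food in group {group!r}"
        )
    total = raw[producible].sum()
    if total <= 0:
        # all producible raw shares zero: split evenly
        shares = producible.astype(float) / producible.sum()
    else:
        shares = raw.where(producible, 0.0) / total
        shares = shares.where(producible, 0.0)
    return shares


def fluid_milk_equivalent(
    dairy_intakes: dict[str, float], compositions: pd.DataFrame
) -> FluidMilkResult:
    """Fluid-milk equivalents from per-food annual dairy masses (lb/yr).

    FM_fat = sum_i intake_i * fat_i / 0.037 and
    FM_nonfat = sum_i intake_i * nonfat_i / 0.086; the larger estimate is
    the limiting dairy fraction and becomes the fluid-milk requirement.
    The non-limiting fraction's surplus is discarded (worksheet ``max``
    semantics), not credited elsewhere.
    """
    comp = compositions.set_index("food_id")
    fm_fat = 0.0
    fm_nonfat = 0.0
    contrib_fat: dict[str, float] = {}
    contrib_nonfat: dict[str, float] = {}
    for food_id, mass in dairy_intakes.items():
        if mass == 0:
            continue
        if food_id not in comp.index:
            raise PipelineError(
                "commodity_flow",
                f"missing dairy composition for consumed food {food_id!r}",
            )
        row = comp.loc[food_id]
        contrib_fat[food_id] = mass * float(row["fat_solids"]) / C.MILK_FAT_SOLIDS
        contrib_nonfat[food_id] = (
            mass * float(row["nonfat_solids"]) / C.MILK_NONFAT_SOLIDS
        )
        fm_fat += contrib_fat[food_id]
        fm_nonfat += contrib_nonfat[food_id]

    if fm_fat == 0 and fm_nonfat == 0:
        return FluidMilkResult(0.0, 0.0, 0.0, "none")
    if fm_fat >= fm_nonfat:
        limiting, fm, contrib = "fat", fm_fat, contrib_fat
    else:
        limiting, fm, contrib = "nonfat", fm_nonfat, contrib_nonfat
    return FluidMilkResult(fm_fat, fm_nonfat, fm, limiting, dict(contrib))


def annual_food_lb(
    servings_per_day: float,
    serving_size_g: float,
    preference_share: float,
    loss_waste_factor: float,
    processing_conversion: float = 1.0,
) -> float:
    """The per-food mass equation: servings/day to lb/person/yr."""
    return (
        servings_per_day
        * serving_size_g
        / C.GRAMS_PER_LB
        * preference_share
        * loss_waste_factor
        * processing_conversion
        * C.DAYS_PER_YEAR
    )


def decompose_fats_oils(
    product_demands: dict[str, float], shares: pd.DataFrame
) -> pd.DataFrame:
    """Split composite fat-product masses into per-oil masses.

    Mass is conserved: per-product oil masses sum to the product mass.
    """
    rows = []
    for product_id, mass in product_demands.items():
        pshares = shares[shares["product_id"] == product_id]
        if pshares.empty:
            raise PipelineError(
                "commodity_flow", f"fat product {product_id!r} has no oil shares"
            )
        for _, r in pshares.iterrows():
            rows.append(
                {
                    "food_id": product_id,
                    "oil_id": r["oil_id"],
                    "mass_lb": mass * float(r["share"]),
                }
            )
    return pd.DataFrame(rows, columns=["food_id", "oil_id", "mass_lb"])


def _loss_waste(food_row: pd.Series, foods: pd.DataFrame, variant: str | None) -> float:
    if variant:
        col = f"loss_waste_factor__{variant}"
        if col in foods.columns and not pd.isna(food_row.get(col)):
            return float(food_row[col])
        log.warning(
            "loss/waste variant %r not available for food %s; using base factor",
            variant,
            food_row["food_id"],
        )
    return float(food_row["loss_waste_factor"])


def food_requirements(
    diet: FoodGroupVector,
    params: FoodSystemParameters,
    include_aquatic_food: bool = True,
    loss_waste_variant: str | None = None,
) -> CommodityDemand:
    """Convert a diet vector into per-food annual commodity demand.

    Dairy foods are routed through :func:`fluid_milk_equivalent` (their
    per-food masses exclude the processing conversion, which is applied to
    the pooled fluid-milk requirement via the fluid-milk food's
    coefficient).  Aquatic foods are split into farmed and wild shares;
    with ``include_aquatic_food=False`` the farmed share is treated as
    wild, removing the aquaculture feed pathway.
    """
    foods = params.foods
    dairy_ids = set(params.dairy["food_id"])
    fat_products = set(params.fats_oils["product_id"])
    species = params.aquaculture.set_index("species_id")

    per_food_rows = []
    dairy_masses: dict[str, float] = {}
    fat_masses: dict[str, float] = {}
    farmed_rows = []
    wild_rows = []

    for group in diet.groups:
        intake = diet.get(group)
        if intake == 0:
            continue
        gdf = foods[foods["food_group"] == group]
        if gdf.empty or not gdf["producible"].any():
            raise PipelineError(
                "commodity_flow",
                f"group {group!r} has intake but no producible foods",
            )
        for _, f in gdf.iterrows():
            share = float(f["preference_share"])
            if share == 0:
                continue
            fid = f["food_id"]
            lw = _loss_waste(f, foods, loss_waste_variant)
            if fid in dairy_ids:
                # pre-processing mass; conversion applied to pooled FM below
                dairy_masses[fid] = annual_food_lb(
                    intake, f["serving_size_g"], share, lw
                )
                continue
            mass = annual_food_lb(
                intake, f["serving_size_g"], share, lw, f["processing_conversion"]
            )
            commodity = f["commodity_id"]
            if commodity in species.index:
                fshare = float(species.loc[commodity, "farmed_share"])
                if not include_aquatic_food:
                    fshare = 0.0
                if fshare > 0:
                    farmed_rows.append(
                        {
                            "food_id": fid,
                            "species_id": commodity,
                            "edible_lb": mass * fshare,
                        }
                    )
                if fshare < 1:
                    wild_rows.append(
                        {"food_id": fid, "edible_lb": mass * (1 - fshare)}
                    )
                continue
            per_food_rows.append(
                {"food_id": fid, "commodity_id": commodity, "mass_lb": mass}
            )
            if fid in fat_products:
                fat_masses[fid] = mass

    dairy = fluid_milk_equivalent(dairy_masses, params.dairy)
    if dairy.fm > 0:
        # the fluid-milk commodity's processing conversion (fluid milk food)
        milk_foods = foods[foods["food_id"].isin(dairy_ids)]
        conv = 1.0
        fm_commodity = "fluid_milk"
        if not milk_foods.empty:
            fm_commodity = milk_foods["commodity_id"].iloc[0]
            fluid_rows = milk_foods[milk_foods["commodity_id"] == fm_commodity]
            conv = float(fluid_rows["processing_conversion"].iloc[0])
        for fid, fm_share in dairy.per_food.items():
            per_food_rows.append(
                {
                    "food_id": fid,
                    "commodity_id": fm_commodity,
                    "mass_lb": fm_share * conv,
                }
            )

    oils = decompose_fats_oils(fat_masses, params.fats_oils)
    return CommodityDemand(
        per_food=pd.DataFrame(
            per_food_rows, columns=["food_id", "commodity_id", "mass_lb"]
        ),
        oils=oils,
        dairy=dairy,
        farmed_fish=pd.DataFrame(
            farmed_rows, columns=["food_id", "species_id", "edible_lb"]
        ),
        wild_aquatic=pd.DataFrame(wild_rows, columns=["food_id", "edible_lb"]),
    )
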