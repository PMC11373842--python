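"""Land availability, grazing-land reallocation, population-fed /
carrying-capacity statistics, total land use, amendment use, and nutrient
summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import constants as C
from .diet_input import FoodGroupVector
from .errors import PipelineError
from .food_system_data import FoodSystemParameters, LandBase
from .land_engine import LandResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandAvailability:
    """Derived land-availability quantities (acres, system level)."""

    cropping_intensity: float
    productive_cropland: float
    proportion_cultivated: float
    available_cultivated_food_cropland: float
    available_grazing_land: float
    available_food_cropland_all_uses: float


@dataclass(frozen=True)
class GrazingAdjustment:
    """Cropland-for-grazing reallocation ratios and quantities.

    ``cropland_used_for_grazing`` and ``grazing_land_offset`` are in the
    same (per-capita) units as the land result they were computed from;
    the offset always equals cropland_used_for_grazing * RY.
    """

    ra: float
    rr: float
    ry: float
    cropland_used_for_grazing: float
    grazing_land_offset: float


@dataclass(frozen=True)
class PopulationFed:
    cultivated_cropland: float
    all_cropland: float
    all_productive_land: float
    carrying_capacity: float
    warning: str | None = None

    def minimum(self) -> float:
        return min(
            self.cultivated_cropland, self.all_cropland, self.all_productive_land
        )


def land_availability(base: LandBase) -> LandAvailability:
    """Evaluate the five availability formulas in order.

    Negative availabilities from inconsistent bases are floored at 0 with
    a warning.
    """
    if not base.total_area_cultivated > 0:
        raise PipelineError(
            "capacity_engine", "total_area_cultivated must be > 0"
        )
    ci = base.area_harvested_field_veg_other / base.total_area_cultivated
    productive = base.cropland_harvested + base.cropland_pasture_grazing
    if productive <= 0:
        raise PipelineError("capacity_engine", "no productive cropland")
    prop_cult = base.total_cultivated_harvested_excl_forage / productive
    avail_cult = productive * prop_cult / ci - base.nonfood_cropland
    if avail_cult < 0:
        log.warning(
            "available cultivated food cropland is negative (%.3f); floored at 0",
            avail_cult,
        )
        avail_cult = 0.0
    avail_grazing = base.permanent_pasture + base.woodland_grazed
    avail_all_uses = productive - base.nonfood_cropland
    if avail_all_uses < 0:
        log.warning("available food cropland (all uses) negative; floored at 0")
        avail_all_uses = 0.0
    return LandAvailability(
        cropping_intensity=ci,
        productive_cropland=productive,
        proportion_cultivated=prop_cult,
        available_cultivated_food_cropland=avail_cult,
        available_grazing_land=avail_grazing,
        available_food_cropland_all_uses=avail_all_uses,
    )


def grazing_adjustment(
    land: LandResult,
    avail: LandAvailability,
    params: FoodSystemParameters,
    ra_basis: str = "all_uses",
) -> GrazingAdjustment:
    """Piecewise cropland-for-grazing reallocation.

    RA = available grazing land / available cropland (``ra_basis`` selects
    all-uses food cropland, the default, or cultivated-only);
    RR = required grazing / (required cultivated / cropping intensity +
    required forage); RY = cropland grazing yield / grazing-land yield,
    so one reallocated cropland acre frees RY acres of pasture and the
    forage mass balance (cropland acres x cropland yield = offset acres x
    grazing yield) holds exactly.
    When RR > RA, cropland_used_for_grazing =
    (required grazing - RA * crop side) / (RA + RY), else 0; the offset is
    cropland_used_for_grazing * RY.
    """
    yield_g = params.yield_for(C.COMMODITY_GRAZED_FORAGE, C.PERMANENT_PASTURE)
    yield_p = params.yield_for(C.COMMODITY_GRAZED_FORAGE, C.CROPLAND_PASTURE)
    if not yield_g or not yield_p:
        raise PipelineError(
            "capacity_engine",
            "grazed forage needs yields on both permanent pasture and cropland",
        )
    ry = yield_p / yield_g

    if ra_basis == "all_uses":
        avail_cropland = avail.available_food_cropland_all_uses
    elif ra_basis == "cultivated":
        avail_cropland = avail.available_cultivated_food_cropland
    else:
        raise ValueError(f"unknown ra_basis {ra_basis!r}")
    if not avail_cropland > 0:
        raise PipelineError("capacity_engine", "available cropland must be > 0")
    ra = avail.available_grazing_land / avail_cropland

    req_grazing = land.total(C.PERMANENT_PASTURE)
    req_cult = land.total(C.CULTIVATED)
    req_forage = land.total(C.CROPLAND_PASTURE)
    crop_side = req_cult / avail.cropping_intensity + req_forage
    if crop_side <= 0:
        if req_grazing > 0:
            raise PipelineError(
                "capacity_engine",
                "zero crop-side denominator with positive grazing demand",
            )
        return GrazingAdjustment(ra=ra, rr=0.0, ry=ry,
                                 cropland_used_for_grazing=0.0,
                                 grazing_land_offset=0.0)
    rr = req_grazing / crop_side
    if rr > ra:
        cropland_grazing = (req_grazing - ra * crop_side) / (ra + ry)
    else:
        cropland_grazing = 0.0
    return GrazingAdjustment(
        ra=ra,
        rr=rr,
        ry=ry,
        cropland_used_for_grazing=cropland_grazing,
        grazing_land_offset=cropland_grazing * ry,
    )


OPEN_TRADE_WARNING = (
    "population-fed estimates assume a fixed domestic land base and are "
    "not recommended under an open trade system"
)


def population_fed(
    land: LandResult,
    avail: LandAvailability,
    adj: GrazingAdjustment,
    population: float,
    trade_mode: str = "closed",
) -> PopulationFed:
    """The three land-constrained population-fed values and carrying
    capacity (their minimum divided by population size).

    A diet needing no land of some type yields an unbounded (+inf)
    population-fed value for that constraint.
    """
    req_cult = land.total(C.CULTIVATED)
    req_forage = land.total(C.CROPLAND_PASTURE)
    req_grazing = land.total(C.PERMANENT_PASTURE)
    ci = avail.cropping_intensity

    def ratio(available: float, per_capita: float) -> float:
        if per_capita <= 0:
            return math.inf
        return available / per_capita

    pf_cult = ratio(avail.available_cultivated_food_cropland, req_cult)
    pf_allcrop = ratio(
        avail.available_food_cropland_all_uses,
        req_cult / ci + req_forage + adj.cropland_used_for_grazing,
    )
    pf_allland = ratio(
        avail.available_food_cropland_all_uses + avail.available_grazing_land,
        req_cult / ci
        + req_forage
        + req_grazing
        + adj.cropland_used_for_grazing
        - adj.grazing_land_offset,
    )
    minimum = min(pf_cult, pf_allcrop, pf_allland)
    cc = minimum / population if math.isfinite(minimum) else math.inf
    warning = OPEN_TRADE_WARNING if trade_mode == "open" else None
    if warning:
        log.warning(warning)
    return PopulationFed(
        cultivated_cropland=pf_cult,
        all_cropland=pf_allcrop,
        all_productive_land=pf_allland,
        carrying_capacity=cc,
        warning=warning,
    )


def total_land_use(
    land: LandResult,
    adj: GrazingAdjustment,
    cropping_intensity: float,
    population: float,
) -> float:
    """Total annual acres: cultivated/CI + (forage + cropland used for
    grazing) + (grazing - grazing offset), scaled to the population."""
    per_capita = (
        land.total(C.CULTIVATED) / cropping_intensity
        + land.total(C.CROPLAND_PASTURE)
        + adj.cropland_used_for_grazing
        + land.total(C.PERMANENT_PASTURE)
        - adj.grazing_land_offset
    )
    return per_capita * population


def adjusted_land_by_type(
    land: LandResult, adj: GrazingAdjustment, cropping_intensity: float
) -> dict[str, float]:
    """Per-capita land by reporting bucket after the grazing reallocation."""
    return {
        "cultivated_cropland": land.total(C.CULTIVATED) / cropping_intensity,
        "cropland_pasture": land.total(C.CROPLAND_PASTURE)
        + adj.cropland_used_for_grazing,
        "permanent_pasture": land.total(C.PERMANENT_PASTURE)
        - adj.grazing_land_offset,
    }


def amendment_use(
    land: LandResult, rates: pd.DataFrame
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-amendment annual totals (per capita) and the per-food breakdown.

    Commodities lacking a rate row contribute 0 with a warning (rates on
    pasture and grazing land are typically zero, so totals are
    conservative).
    """
    if (rates["rate"] < 0).any():
        raise PipelineError("capacity_engine", "negative amendment rate")
    rate_map = {
        (r["commodity_id"], r["amendment"]): float(r["rate"])
        for _, r in rates.iterrows()
    }
    rated_commodities = set(rates["commodity_id"])
    rows = []
    missing: set[str] = set()
    for _, r in land.table.iterrows():
        commodity = r["commodity_id"]
        if commodity not in rated_commodities:
            missing.add(commodity)
        for amendment in C.AMENDMENTS:
            rate = rate_map.get((commodity, amendment), 0.0)
            rows.append(
                {
                    "food_id": r["food_id"],
                    "commodity_id": commodity,
                    "amendment": amendment,
                    "quantity": float(r["acres"]) * rate,
                }
            )
    if missing:
        log.warning(
            "no amendment rates for commodities %s; contributing 0 "
            "(conservative estimate)",
            sorted(missing),
        )
    breakdown = pd.DataFrame(
        rows, columns=["food_id", "commodity_id", "amendment", "quantity"]
    )
    totals = {
        a: (
            float(breakdown[breakdown["amendment"] == a]["quantity"].sum())
            if not breakdown.empty
            else 0.0
        )
        for a in C.AMENDMENTS
    }
    return totals, breakdown


def nutrient_summary(
    diet: FoodGroupVector, params: FoodSystemParameters
) -> dict[str, float]:
    """Per-capita daily energy/macros: sum over foods of servings times
    per-serving composition.  Foods without composition are skipped with
    a warning."""
    comp = params.nutrients.set_index("food_id")
    totals = {"energy_kcal": 0.0, "protein_g": 0.0, "fat_g": 0.0,
              "carbohydrate_g": 0.0}
    for group in diet.groups:
        intake = diet.get(group)
        if intake == 0:
            continue
        for _, f in params.foods_in_group(group).iterrows():
            share = float(f["preference_share"])
            if share == 0:
                continue
            fid = f["food_id"]
            if fid not in comp.index:
                log.warning("no nutrient composition for %s; skipped", fid)
                continue
            servings = intake * share
            for key in totals:
                totals[key] += servings * float(comp.loc[fid, key])
    return totals


@dataclass
class FootprintResult:
    """Full per-diet output: land, amendments, capacity, nutrients."""

    demand: object
    feed: pd.DataFrame
    multiuse: object
    land: LandResult
    availability: LandAvailability
    grazing: GrazingAdjustment
    population_fed: PopulationFed
    total_land_acres: float
    land_by_type: dict[str, float]
    amendments: dict[str, float]
    amendment_breakdown: pd.DataFrame
    nutrients: dict[str, float]
    population: float
    trade_mode: str
    warnings: list[str] = field(default_factory=list)

    @property
    def carrying_capacity(self) -> float:
        return self.population_fed.carrying_capacity

    def land_total_per_capita(self) -> float:
        return self.total_land_acres / self.population

    def fertilizer_total(self) -> float:
        return sum(self.amendments[n] for n in C.FERTILIZER_NUTRIENTS)

    def resource_totals(self) -> dict[str, float]:
        """Per-capita totals used by the 3-SD outlier screen."""
        return {
            "land": self.land_total_per_capita(),
            "fertilizer": self.fertilizer_total(),
            "pesticides": self.amendments["pesticides"],
            "irrigation": self.amendments["irrigation"],
        }

    def to_si(self) -> dict[str, float]:
        """Report-layer SI conversions (ha, kg, m3)."""
        out = {"land_total_ha": self.total_land_acres * C.ACRES_TO_HA}
        for name in C.FERTILIZER_NUTRIENTS + ("pesticides",):
            out[f"{name}_kg"] = self.amendments[name] * C.LB_TO_KG
        out["irrigation_m3"] = self.amendments["irrigation"] * C.ACRE_FT_TO_M3
        return out
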