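"""Feed-commodity demand for animal products and per-food trade balances.

Livestock feed coefficients are taken as input data; the aquaculture
requirement is computed here from feed-conversion ratio, processing
efficiency, and ration nutrient density, with a two-ingredient
(corn + soybean meal) solve of the energy/protein system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .commodity_flow import CommodityDemand
from .errors import PipelineError
from .food_system_data import FoodSystemParameters

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AquacultureRequirement:
    """Per-edible-lb nutrient requirements and the corn/soymeal blend."""

    species_id: str
    energy_required: float
    protein_required: float
    corn_lb: float
    soymeal_lb: float
    exact: bool  # False when a negative exact solution was clipped


def aquaculture_requirements(
    species: pd.Series,
    feed_nutrients: pd.DataFrame,
    mode: str = "corrected",
) -> AquacultureRequirement:
    """Solve the corn/soybean-meal blend for one farmed species.

    Feed mass per lb edible fish is FCR / processing_efficiency (lb feed
    per lb live times lb live per lb edible).  ``mode='strict_paper'``
    instead multiplies FCR by processing efficiency, reproducing the
    printed dimensional form for comparison.  The 2x2 energy/protein
    system is solved exactly; a negative component is clipped to zero and
    the remaining ingredient sized to meet both requirements (least-excess
    blend), with a warning.
    """
    eff = float(species["processing_efficiency"])
    if not eff > 0:
        raise PipelineError("feed_trade", "nonpositive processing efficiency")
    fcr = float(species["fcr"])
    feed_per_edible = fcr * eff if mode == "strict_paper" else fcr / eff
    e_req = feed_per_edible * float(species["ration_energy"])
    p_req = feed_per_edible * float(species["ration_protein"])

    fn = feed_nutrients.set_index("feed_commodity_id")
    try:
        corn = fn.loc[C.COMMODITY_CORN]
        soy = fn.loc[C.COMMODITY_SOYBEAN_MEAL]
    except KeyError as exc:
        raise PipelineError(
            "feed_trade", f"missing feed nutrient content for {exc.args[0]!r}"
        ) from exc

    a = np.array(
        [
            [float(corn["energy_per_lb"]), float(soy["energy_per_lb"])],
            [float(corn["protein_per_lb"]), float(soy["protein_per_lb"])],
        ]
    )
    if abs(np.linalg.det(a)) < 1e-12:
        raise PipelineError("feed_trade", "singular feed nutrient matrix")
    corn_lb, soymeal_lb = np.linalg.solve(a, np.array([e_req, p_req]))

    exact = True
    if corn_lb < 0 or soymeal_lb < 0:
        exact = False
        log.warning(
            "aquaculture %s: exact blend has a negative component; "
            "clipping to the nonnegative least-excess blend",
            species["species_id"],
        )
        if corn_lb < 0:
            corn_lb = 0.0
            soymeal_lb = max(
                e_req / a[0, 1] if a[0, 1] > 0 else 0.0,
                p_req / a[1, 1] if a[1, 1] > 0 else 0.0,
            )
        else:
            soymeal_lb = 0.0
            corn_lb = max(
                e_req / a[0, 0] if a[0, 0] > 0 else 0.0,
                p_req / a[1, 0] if a[1, 0] > 0 else 0.0,
            )
    return AquacultureRequirement(
        species_id=str(species["species_id"]),
        energy_required=e_req,
        protein_required=p_req,
        corn_lb=float(corn_lb),
        soymeal_lb=float(soymeal_lb),
        exact=exact,
    )


def livestock_feed_demand(
    demand: CommodityDemand,
    params: FoodSystemParameters,
    aquaculture_mode: str = "corrected",
) -> pd.DataFrame:
    """Feed-commodity demand per food (lb/person/yr).

    Linear in animal-product demand: feed mass = product mass times the
    coefficient, summed per feed commodity.  Farmed aquatic demand is
    appended via :func:`aquaculture_requirements` per species.

    Returns a frame with columns food_id, feed_commodity_id, mass_lb.
    """
    coeffs = params.feed
    animal_products = set(coeffs["animal_product_id"])
    rows = []
    for _, r in demand.per_food.iterrows():
        commodity = r["commodity_id"]
        if commodity not in animal_products:
            continue
        for _, fc in coeffs[coeffs["animal_product_id"] == commodity].iterrows():
            rows.append(
                {
                    "food_id": r["food_id"],
                    "feed_commodity_id": fc["feed_commodity_id"],
                    "mass_lb": float(r["mass_lb"])
                    * float(fc["lb_feed_per_lb_product"]),
                }
            )

    species_df = params.aquaculture.set_index("species_id", drop=False)
    for _, r in demand.farmed_fish.iterrows():
        if r["species_id"] not in species_df.index:
            raise PipelineError(
                "feed_trade", f"unknown aquaculture species {r['species_id']!r}"
            )
        req = aquaculture_requirements(
            species_df.loc[r["species_id"]],
            params.feed_nutrients,
            mode=aquaculture_mode,
        )
        edible = float(r["edible_lb"])
        if req.corn_lb > 0:
            rows.append(
                {
                    "food_id": r["food_id"],
                    "feed_commodity_id": C.COMMODITY_CORN,
                    "mass_lb": edible * req.corn_lb,
                }
            )
        if req.soymeal_lb > 0:
            rows.append(
                {
                    "food_id": r["food_id"],
                    "feed_commodity_id": C.COMMODITY_SOYBEAN_MEAL,
                    "mass_lb": edible * req.soymeal_lb,
                }
            )
    df = pd.DataFrame(rows, columns=["food_id", "feed_commodity_id", "mass_lb"])
    if not df.empty:
        df = (
            df.groupby(["food_id", "feed_commodity_id"], as_index=False)["mass_lb"]
            .sum()
        )
    return df


def trade_balance(
    trade: pd.DataFrame,
    mode: str = "open",
    sign_mode: str = "narrative",
) -> pd.DataFrame:
    """System-level annual trade balance per food (lb/yr).

    In the default (narrative) sign convention the balance is
    stock + imports - exports: a positive balance means fewer domestic
    commodities are needed, a negative one means more.  ``sign_mode=
    'printed'`` adds exports instead, reproducing the printed equation.
    Closed mode short-circuits to all-zero balances.
    """
    df = trade[["food_id"]].copy()
    if mode == "closed":
        df["balance"] = 0.0
        return df
    sign = -1.0 if sign_mode == "narrative" else 1.0
    df["balance"] = (
        trade["beginning_stock"].astype(float)
        + trade["imports"].astype(float)
        + sign * trade["exports"].astype(float)
    )
    return df


def apply_trade_balances(
    demand: CommodityDemand,
    balances: pd.DataFrame,
    population: float,
) -> CommodityDemand:
    """Scale each food's demand by its per-capita trade balance.

    The food's net commodity requirement is max(0, mass - balance/pop);
    all of the food's routing rows (commodity, oils, farmed fish) scale by
    the same factor so downstream feed expansion stays consistent.  A
    trade surplus can at most zero a food's requirement, never make it
    negative.
    """
    if not population > 0:
        raise PipelineError("feed_trade", "population must be > 0")
    bal = dict(zip(balances["food_id"], balances["balance"].astype(float)))
    if not bal or all(v == 0 for v in bal.values()):
        return demand

    gross = {
        fid: demand.food_mass(fid)
        for fid in set(demand.per_food["food_id"])
    }
    for _, r in demand.farmed_fish.iterrows():
        gross[r["food_id"]] = gross.get(r["food_id"], 0.0) + float(r["edible_lb"])
    for _, r in demand.wild_aquatic.iterrows():
        gross[r["food_id"]] = gross.get(r["food_id"], 0.0) + float(r["edible_lb"])

    def factor(fid: str) -> float:
        b = bal.get(fid, 0.0)
        m = gross.get(fid, 0.0)
        if b == 0 or m == 0:
            return 1.0
        return max(0.0, (m - b / population) / m)

    per_food = demand.per_food.copy()
    per_food["mass_lb"] = [
        float(r["mass_lb"]) * factor(r["food_id"]) for _, r in per_food.iterrows()
    ]
    oils = demand.oils.copy()
    if not oils.empty:
        oils["mass_lb"] = [
            float(r["mass_lb"]) * factor(r["food_id"]) for _, r in oils.iterrows()
        ]
    farmed = demand.farmed_fish.copy()
    if not farmed.empty:
        farmed["edible_lb"] = [
            float(r["edible_lb"]) * factor(r["food_id"])
            for _, r in farmed.iterrows()
        ]
    return CommodityDemand(
        per_food=per_food,
        oils=oils,
        dairy=demand.dairy,
        farmed_fish=farmed,
        wild_aquatic=demand.wild_aquatic,
    )
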