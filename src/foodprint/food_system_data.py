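"""Read, validate, and write the food-system parameter set.

The canonical on-disk format is one UTF-8 delimited table per logical
worksheet plus a ``manifest.yaml`` naming each table.  Every invariant on
every table is machine-checked at load time; violations are fatal and
reported together.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import constants as C
from .errors import ParameterError

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.yaml"

#: table name -> (filename, required columns)
TABLE_SPECS: dict[str, tuple[str, list[str]]] = {
    "foods": (
        "foods.tsv",
        [
            "food_id", "food_group", "category", "serving_size_g",
            "serving_unit", "producible", "preference_share_raw",
            "preference_share", "loss_waste_factor", "processing_conversion",
            "commodity_id",
        ],
    ),
    "dairy": ("dairy.tsv", ["food_id", "fat_solids", "nonfat_solids"]),
    "fats_oils": ("fats_oils.tsv", ["product_id", "oil_id", "share"]),
    "feed": (
        "feed.tsv",
        ["animal_product_id", "feed_commodity_id", "lb_feed_per_lb_product"],
    ),
    "aquaculture": (
        "aquaculture.tsv",
        [
            "species_id", "farmed_share", "fcr", "processing_efficiency",
            "ration_energy", "ration_protein",
        ],
    ),
    "feed_nutrients": (
        "feed_nutrients.tsv",
        ["feed_commodity_id", "energy_per_lb", "protein_per_lb"],
    ),
    "trade": ("trade.tsv", ["food_id", "beginning_stock", "imports", "exports"]),
    "yields": ("yields.tsv", ["commodity_id", "land_type", "yield_lb_per_acre"]),
    "amendments": ("amendments.tsv", ["commodity_id", "amendment", "rate"]),
    "land_base": ("land_base.tsv", None),  # single-row, fixed columns below
    "nutrients": (
        "nutrients.tsv",
        ["food_id", "energy_kcal", "protein_g", "fat_g", "carbohydrate_g"],
    ),
    "oilseeds": (
        "oilseeds.tsv",
        ["oilseed_id", "oil_id", "oil_yield", "meal_yield", "meal_protein"],
    ),
    "fat_coproducts": (
        "fat_coproducts.tsv",
        ["animal_product_id", "lard_tallow_per_lb"],
    ),
}

LAND_BASE_FIELDS = [
    "area_harvested_field_veg_other",
    "total_area_cultivated",
    "cropland_harvested",
    "cropland_pasture_grazing",
    "total_cultivated_harvested_excl_forage",
    "nonfood_cropland",
    "permanent_pasture",
    "woodland_grazed",
]


@dataclass(frozen=True)
class LandBase:
    """Physical land areas of the study region, in acres."""

    area_harvested_field_veg_other: float
    total_area_cultivated: float
    cropland_harvested: float
    cropland_pasture_grazing: float
    total_cultivated_harvested_excl_forage: float
    nonfood_cropland: float
    permanent_pasture: float
    woodland_grazed: float


@dataclass
class FoodSystemParameters:
    """The full per-food and system-level coefficient set.

    Each attribute mirrors one worksheet-equivalent table; see
    :data:`TABLE_SPECS` for column contracts.  ``foods.preference_share``
    holds the producible-reapportioned shares; the raw (pre-reapportionment)
    shares are retained in ``preference_share_raw`` for provenance.
    """

    foods: pd.DataFrame
    dairy: pd.DataFrame
    fats_oils: pd.DataFrame
    feed: pd.DataFrame
    aquaculture: pd.DataFrame
    feed_nutrients: pd.DataFrame
    trade: pd.DataFrame
    yields: pd.DataFrame
    amendments: pd.DataFrame
    land_base: LandBase
    nutrients: pd.DataFrame
    oilseeds: pd.DataFrame
    fat_coproducts: pd.DataFrame
    food_groups: tuple[str, ...] = field(default=C.FOOD_GROUPS)

    # ---- convenience lookups -------------------------------------------

    def food(self, food_id: str) -> pd.Series:
        rows = self.foods[self.foods["food_id"] == food_id]
        if rows.empty:
            raise KeyError(food_id)
        return rows.iloc[0]

    def foods_in_group(self, group: str) -> pd.DataFrame:
        return self.foods[self.foods["food_group"] == group]

    def yield_for(self, commodity_id: str, land_type: str) -> float | None:
        rows = self.yields[
            (self.yields["commodity_id"] == commodity_id)
            & (self.yields["land_type"] == land_type)
        ]
        return None if rows.empty else float(rows["yield_lb_per_acre"].iloc[0])

    def primary_land_type(self, commodity_id: str) -> str | None:
        """Land type a commodity's demand is charged to.

        Grazed forage carries two yield rows (permanent pasture plus the
        cropland yield used only for the grazing reallocation ratio); its
        demand is charged to permanent pasture.
        """
        rows = self.yields[self.yields["commodity_id"] == commodity_id]
        if rows.empty:
            return None
        types = set(rows["land_type"])
        if len(types) == 1:
            return rows["land_type"].iloc[0]
        if C.PERMANENT_PASTURE in types:
            return C.PERMANENT_PASTURE
        raise ParameterError(
            f"commodity {commodity_id!r} has multiple yield rows with no "
            f"permanent-pasture row to disambiguate"
        )

    def equals(self, other: "FoodSystemParameters") -> bool:
        if self.food_groups != other.food_groups:
            return False
        if self.land_base != other.land_base:
            return False
        for name in TABLE_SPECS:
            if name == "land_base":
                continue
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            try:
                pd.testing.assert_frame_equal(a, b, check_dtype=False)
            except AssertionError:
                return False
        return True


# ---------------------------------------------------------------------------
# validation


def validate_parameters(params: FoodSystemParameters) -> list[str]:
    """Check every declared invariant; return a list of problem strings."""
    problems: list[str] = []
    foods = params.foods

    if foods["food_id"].duplicated().any():
        dupes = foods.loc[foods["food_id"].duplicated(), "food_id"].tolist()
        problems.append(f"duplicate food_id(s): {dupes}")

    for _, r in foods.iterrows():
        fid = r["food_id"]
        if not r["serving_size_g"] > 0:
            problems.append(f"food {fid}: serving_size_g must be > 0")
        if not r["loss_waste_factor"] >= 1:
            problems.append(f"food {fid}: loss_waste_factor must be >= 1")
        if not r["processing_conversion"] > 0:
            problems.append(f"food {fid}: processing_conversion must be > 0")
        for col in ("preference_share_raw", "preference_share"):
            if not 0 <= r[col] <= 1:
                problems.append(f"food {fid}: {col} outside [0, 1]")
        if r["food_group"] not in params.food_groups:
            problems.append(f"food {fid}: unknown food_group {r['food_group']!r}")

    # reapportioned preference shares sum to 1 over producible foods
    for group, gdf in foods.groupby("food_group"):
        prod = gdf[gdf["producible"]]
        if prod.empty:
            continue
        total = prod["preference_share"].sum()
        if abs(total - 1.0) > 1e-9:
            problems.append(
                f"group {group}: producible preference shares sum to {total!r}"
            )
        nonprod = gdf[~gdf["producible"]]
        if (nonprod["preference_share"] != 0).any():
            problems.append(
                f"group {group}: non-producible food has nonzero preference_share"
            )

    known_foods = set(foods["food_id"])
    for _, r in params.dairy.iterrows():
        fid = r["food_id"]
        if fid not in known_foods:
            problems.append(f"dairy: unknown food {fid}")
        if r["fat_solids"] < 0 or r["nonfat_solids"] < 0:
            problems.append(f"dairy {fid}: negative solids fraction")
        if r["fat_solids"] + r["nonfat_solids"] > 1 + 1e-12:
            problems.append(f"dairy {fid}: solids fractions sum above 1")

    for product, pdf in params.fats_oils.groupby("product_id"):
        total = pdf["share"].sum()
        if abs(total - 1.0) > 1e-9:
            problems.append(f"fat product {product}: shares sum to {total!r}")

    if (params.feed["lb_feed_per_lb_product"] < 0).any():
        problems.append("feed: negative lb_feed_per_lb_product")

    for _, r in params.aquaculture.iterrows():
        sid = r["species_id"]
        if not 0 <= r["farmed_share"] <= 1:
            problems.append(f"aquaculture {sid}: farmed_share outside [0, 1]")
        if not r["fcr"] > 0:
            problems.append(f"aquaculture {sid}: fcr must be > 0")
        if not 0 < r["processing_efficiency"] <= 1:
            problems.append(
                f"aquaculture {sid}: processing_efficiency outside (0, 1]"
            )

    for col in ("beginning_stock", "imports", "exports"):
        if (params.trade[col] < 0).any():
            problems.append(f"trade: negative {col}")
    bad_trade = set(params.trade["food_id"]) - known_foods
    if bad_trade:
        problems.append(f"trade: unknown food(s) {sorted(bad_trade)}")

    for _, r in params.yields.iterrows():
        if r["land_type"] not in C.LAND_TYPES:
            problems.append(f"yields: unknown land_type {r['land_type']!r}")
        if not r["yield_lb_per_acre"] > 0:
            problems.append(
                f"yields {r['commodity_id']}/{r['land_type']}: yield must be > 0"
            )
    if params.yields.duplicated(["commodity_id", "land_type"]).any():
        problems.append("yields: duplicate (commodity_id, land_type) rows")

    for _, r in params.amendments.iterrows():
        if r["amendment"] not in C.AMENDMENTS:
            problems.append(f"amendments: unknown amendment {r['amendment']!r}")
        if r["rate"] < 0:
            problems.append(
                f"amendments {r['commodity_id']}/{r['amendment']}: negative rate"
            )

    for name in LAND_BASE_FIELDS:
        if getattr(params.land_base, name) < 0:
            problems.append(f"land_base: {name} must be >= 0")

    bad_nut = set(params.nutrients["food_id"]) - known_foods
    if bad_nut:
        problems.append(f"nutrients: unknown food(s) {sorted(bad_nut)}")

    for df, col in ((params.oilseeds, "oil_yield"), (params.oilseeds, "meal_yield")):
        if (df[col] < 0).any() or (df[col] > 1).any():
            problems.append(f"oilseeds: {col} outside [0, 1]")
    if (params.fat_coproducts["lard_tallow_per_lb"] < 0).any():
        problems.append("fat_coproducts: negative lard_tallow_per_lb")

    # cross-reference: any commodity with a primary land use must have a yield
    for value in (params.feed["feed_commodity_id"],):
        for commodity in set(value):
            if commodity == C.COMMODITY_SOYBEAN_MEAL:
                commodity = C.COMMODITY_SOYBEANS
            if params.primary_land_type(commodity) is None:
                problems.append(
                    f"feed commodity {commodity!r} has no yield row"
                )

    for v in vars(params).values():
        if isinstance(v, pd.DataFrame):
            num = v.select_dtypes("number")
            if not num.empty and not num.map(math.isfinite).all().all():
                problems.append("non-finite value in a parameter table")

    return problems


# ---------------------------------------------------------------------------
# i/o


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    filename, columns = TABLE_SPECS[name]
    path = directory / filename
    if not path.exists():
        raise ParameterError(f"missing parameter table: {filename}")
    df = pd.read_csv(path, sep="\t")
    required = LAND_BASE_FIELDS if name == "land_base" else columns
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"table {filename}: missing column(s) {missing}")
    for col in df.columns:
        if pd.api.types.is_integer_dtype(df[col]):
            df[col] = df[col].astype(float)
    return df


def load_parameters(path: str | Path) -> FoodSystemParameters:
    """Load and validate a parameter directory.

    Parameters
    ----------
    path
        Directory containing the delimited tables and ``manifest.yaml``.

    Raises
    ------
    ParameterError
        If a table is missing, a column is absent, or any invariant fails.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise ParameterError(f"parameter path is not a directory: {directory}")

    manifest_path = directory / MANIFEST_NAME
    food_groups = C.FOOD_GROUPS
    if manifest_path.exists():
        manifest = yaml.safe_load(manifest_path.read_text()) or {}
        if "food_groups" in manifest:
            food_groups = tuple(manifest["food_groups"])

    tables = {name: _read_table(directory, name) for name in TABLE_SPECS}
    lb_row = tables.pop("land_base").iloc[0]
    land_base = LandBase(**{k: float(lb_row[k]) for k in LAND_BASE_FIELDS})

    params = FoodSystemParameters(
        land_base=land_base, food_groups=food_groups, **tables
    )
    problems = validate_parameters(params)
    if problems:
        raise ParameterError(
            "parameter validation failed:\n  " + "\n  ".join(problems)
        )
    log.info("loaded %d foods from %s; validation passed", len(params.foods), path)
    return params


def write_parameters(params: FoodSystemParameters, path: str | Path) -> None:
    """Write a parameter set as delimited tables + manifest.

    Round-trip guarantee: ``load_parameters`` on the written directory
    returns a parameter set equal field-for-field to ``params``.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "foodprint-parameters-v1",
        "food_groups": list(params.food_groups),
        "tables": {name: fn for name, (fn, _) in TABLE_SPECS.items()},
    }
    (directory / MANIFEST_NAME).write_text(yaml.safe_dump(manifest, sort_keys=False))
    for name, (filename, _) in TABLE_SPECS.items():
        if name == "land_base":
            df = pd.DataFrame([vars(params.land_base)])
        else:
            df = getattr(params, name)
        df.to_csv(directory / filename, sep="\t", index=False)


def load_workbook(path: str | Path) -> FoodSystemParameters:  # pragma: no cover
    """Thin read-only importer for a spreadsheet distribution of the
    parameter set (requires ``openpyxl``).

    Expects one sheet per table named as in :data:`TABLE_SPECS` with the
    same column headers; the spreadsheet is a distribution artifact, not
    the data model, so anything richer should be exported to the delimited
    format first.
    """
    tables = {}
    for name, (_, _) in TABLE_SPECS.items():
        df = pd.read_excel(path, sheet_name=name)
        for col in df.columns:
            if pd.api.types.is_integer_dtype(df[col]):
                df[col] = df[col].astype(float)
        tables[name] = df
    lb_row = tables.pop("land_base").iloc[0]
    land_base = LandBase(**{k: float(lb_row[k]) for k in LAND_BASE_FIELDS})
    params = FoodSystemParameters(land_base=land_base, **tables)
    problems = validate_parameters(params)
    if problems:
        raise ParameterError(
            "parameter validation failed:\n  " + "\n  ".join(problems)
        )
    return params


def with_reapportioned_shares(params: FoodSystemParameters) -> FoodSystemParameters:
    """Return a copy whose ``preference_share`` column is recomputed from
    the raw shares by zeroing non-producible foods and renormalizing
    producible foods proportionally (see commodity_flow.reapportion_preferences).
    """
    from .commodity_flow import reapportion_preferences

    foods = params.foods.copy()
    for group in foods["food_group"].unique():
        mask = foods["food_group"] == group
        foods.loc[mask, "preference_share"] = reapportion_preferences(
            foods.loc[mask]
        ).to_numpy()
    return replace(params, foods=foods)
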