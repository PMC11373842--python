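"""Unit constants and canonical identifiers shared across the model.

All internal computation uses imperial/customary units (lb, acres,
servings/day); SI conversion happens only when a report is rendered.
"""

# mass / time
GRAMS_PER_LB = 454.0
DAYS_PER_YEAR = 365.0

# fluid-milk solids content (mass fractions of whole fluid milk)
MILK_FAT_SOLIDS = 0.037
MILK_NONFAT_SOLIDS = 0.086

# SI reporting conversions
ACRES_TO_HA = 0.404686
LB_TO_KG = 0.453592
ACRE_FT_TO_M3 = 1233.48

# land types
CULTIVATED = "cultivated_cropland"
CROPLAND_PASTURE = "cropland_pasture"
PERMANENT_PASTURE = "permanent_pasture"
LAND_TYPES = (CULTIVATED, CROPLAND_PASTURE, PERMANENT_PASTURE)

# amendments
AMENDMENTS = ("N", "P2O5", "K2O", "S", "pesticides", "irrigation")
FERTILIZER_NUTRIENTS = ("N", "P2O5", "K2O", "S")

# reserved commodity identifiers with special routing
COMMODITY_GRAZED_FORAGE = "grazed_forage"
COMMODITY_SOYBEAN_MEAL = "soybean_meal"
COMMODITY_SOYBEANS = "soybeans"
COMMODITY_CORN = "corn"
COMMODITY_LARD_TALLOW = "lard_tallow"
OIL_CORN = "corn_oil"

# canonical 22 food groups accepted on the diet-input surface
FOOD_GROUPS = (
    "grains",
    "fruit",
    "dark_green_vegetables",
    "red_orange_vegetables",
    "beans_peas_lentils",
    "starchy_vegetables",
    "other_vegetables",
    "fluid_milk_yogurt",
    "cheese_other_dairy",
    "soy_milk",
    "nuts",
    "tofu",
    "beef",
    "pork",
    "chicken",
    "turkey",
    "eggs",
    "aquatic_food",
    "plant_oils",
    "dairy_fats",
    "lard_tallow",
    "sweeteners",
)
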