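"""Build a small food-composition table, resolve sentinel codes, and compute
recipe nutrients per 100 g.

Run:  python examples/01_fct_and_recipes.py
"""

import tempfile
from pathlib import Path

from dietrecall import (
    FCTable,
    FctContext,
    FoodItem,
    NutrientVector,
    Recipe,
    RecipeRegistry,
    UNKNOWN_CODE,
    load_fct,
    recipe_nutrients_per_100g,
)

FCT_TEXT = """\
code,name,food_group,edible_fraction,energy_kcal,protein_g,animal_protein_g,fat_g,carb_g,fiber,calcium_mg,iron_mg,zinc_mg,vitA_ug_RE,folate_ug
T001,maize ugali,cereals,1.0,112.0,3.1,0.0,0.5,23.0,1.2,8.0,0.9,0.6,0.0,18.0
T002,fish relish with oil,meat_fish,0.8,190.0,18.5,17.0,12.0,1.5,0.0,120.0,1.4,1.1,20.0,8.0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "fct.csv"
    path.write_text(FCT_TEXT)
    primary = load_fct(path, "primary")

# a secondary table standing in for the neighbouring country's FCT used to
# resolve unknown meals
secondary = FCTable(source_label="secondary")
secondary.add(
    FoodItem(
        "K100", "octopus stew", "meat_fish",
        NutrientVector(energy_kcal=82, protein_g=15, animal_protein_g=15),
        1.0,
    )
)

# an unknown meal (sentinel 9999) manually assigned to the secondary table
ctx = FctContext(
    primary=primary,
    secondary=secondary,
    assignments={"octopus stew": "K100"},
)
resolved = ctx.resolve(UNKNOWN_CODE, "octopus stew")
print(f"unknown meal resolved from: {resolved.source}  ({resolved.audit})")

# a new recipe: 300 g ugali + 150 g fish relish cooked down to 400 g.
# Per 100 g of dish: each ingredient contributes raw grams x edible fraction
# x per-100 g content / 100, renormalised by the cooked weight.
recipe = Recipe.build(
    "R001",
    "ugali na samaki",
    [("T001", 300.0), ("T002", 150.0)],
    cooked_weight_g=400.0,
    source_doc="field notebook",
)
RecipeRegistry().register(recipe)
vec = recipe_nutrients_per_100g(recipe, ctx)
print(f"recipe energy per 100 g: {vec.energy_kcal:.1f} kcal")
print(f"recipe protein per 100 g: {vec.protein_g:.1f} g "
      f"(animal-source {vec.animal_protein_g:.1f} g)")
# the energy value is (300*1.0*112 + 150*0.8*190)/100 / 400 * 100 = 141.0
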