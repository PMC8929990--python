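"""Independent brute-force recomputation of person-day nutrient totals.

Reads the raw delimited files with the csv module only and applies the
nutrient arithmetic directly — deliberately not importing the package's
nutrient pipeline, so it can serve as an oracle for it.
"""

import csv

NUTRIENTS = (
    "energy_kcal", "protein_g", "animal_protein_g", "fat_g", "carb_g",
    "fiber", "calcium_mg", "iron_mg", "zinc_mg", "vitA_ug_RE", "folate_ug",
)


def _read(path):
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def bruteforce_totals(demog_csv, meals_csv, fct_csv, portion_csv):
    """Person-day totals: dict (participant_id, recall_date) -> nutrient dict.

    Breast-milk rows are skipped; grams = portion_count * grams_per_unit
    (food-specific portion key first, then the food-group default); each row
    contributes grams * edible_fraction / 100 * per-100 g content.
    """
    fct = {}
    for row in _read(fct_csv):
        fct[row["code"]] = {
            "food_group": row["food_group"],
            "ef": float(row["edible_fraction"]),
            "per100": {n: float(row[n]) for n in NUTRIENTS},
        }
    portions = {}
    for row in _read(portion_csv):
        portions[(row["food_code_or_group"], row["utensil"], row["size"])] = float(
            row["grams_per_unit"]
        )

    totals = {}
    for row in _read(demog_csv):
        totals[(row["participant_id"], row["recall_date"])] = {
            n: 0.0 for n in NUTRIENTS
        }
    for row in _read(meals_csv):
        key = (row["participant_id"], row["recall_date"])
        if row["is_breastmilk"].strip().lower() in {"true", "yes", "1"}:
            continue
        food = fct[row["food_code"]]
        pkey = (row["food_code"], row["utensil"], row["utensil_size"])
        if pkey in portions:
            gpu = portions[pkey]
        else:
            gpu = portions[(food["food_group"], row["utensil"], row["utensil_size"])]
        grams = float(row["portion_count"]) * gpu
        scale = grams * food["ef"] / 100.0
        for n in NUTRIENTS:
            totals[key][n] += scale * food["per100"][n]
    return totals
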