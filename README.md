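# dietrecall

Processing back end for tablet-based 24-hour dietary recalls, built for the
kind of two-table export produced by interviewer-administered, multiple-pass
recall tools used in East African field studies (peri-urban adults and rural
children under two). It takes the raw export — one demographics record per
participant-day plus one row per consumed item — and turns it into quality-
controlled, per-meal and per-day nutrient intakes with meal-structure,
chrono-nutrition and food-away-from-home analytics.

## What it does

* **Food-composition linkage.** Food codes resolve against a primary
  food-composition table (FCT); the sentinel code `9999` (unknown meal)
  resolves through an explicit, reviewable assignment table to a secondary
  FCT or to a field-captured recipe (`8888`). Recipe nutrients are computed
  per 100 g of dish: for nutrient *n*,

      total_n = Σ_i  g_i · EP_i · c_i(n) / 100,      result_n = 100 · total_n / W

  where `g_i` are raw ingredient grams, `EP_i` edible fractions, `c_i(n)`
  per-100 g content, and `W` the cooked weight (raw total when absent). No
  retention factors are applied.
* **Portion-to-gram conversion.** Reports against seven reference utensils
  (bowl, cup, tumbler, plate, tablespoon, teaspoon, saucer) with size
  classes convert via a portion-size database keyed by
  `(food code or food group, utensil, size)`; food-specific entries take
  precedence over group defaults, and every conversion carries its audit
  trail.
* **Nutrient intakes.** Per meal record:
  `intake = grams · EP / 100 × per-100 g vector` over eleven nutrients
  (energy, protein, animal-source protein, fat, carbohydrate, fiber,
  calcium, iron, zinc, vitamin A in μg RE, folate). Breast-milk entries
  carry timing and frequency but never nutrients; unresolved codes
  contribute zero and are counted per day. Daily totals screen against an
  editable Recommended Nutrient Intake table (iron at 10% bioavailability,
  zinc at moderate bioavailability, a breast-milk-adjusted folate RNI of
  27.6 μg/d for 9–11 mo) and, for breastfed children, against the
  acceptable energy ranges 100–600 kcal (6–8 mo), 200–750 kcal (9–11 mo)
  and 500–1100 kcal (12–23 mo).
* **Quality control.** Field-supervision rules: declared breastfeeding
  frequency must equal the number of breast-milk meal entries; a
  "two-mornings" heuristic catches recalls spanning 08:00-to-08:00;
  inter-meal gaps over 6 h, implausible portion grams per age class, and
  foods outside a regional availability list are flagged. Deterministic
  interview summaries, daily field reports and per-person dietary profiles.
* **Meal-structure analytics.** A meal is everything consumed at the same
  recorded time; groups rank into meal-order positions driving meal
  frequency (with and without breastfeeding), timing histograms, energy by
  meal order per stratum, the away-from-home share of daily energy, and
  food-frequency rankings.
* **Synthetic cohorts.** A seeded generator emulates both study populations
  (gendered eating-out behaviour, age-graded breastfeeding and meal
  frequency) and can plant known QC faults, returning the ground truth for
  exact recovery tests. No study data ship with the package.

## Worked example

```python
from dietrecall import SimConfig, generate_cohort, compute_intakes, fafh_summary

cohort, ctx, portion_db, utensils = generate_cohort(SimConfig(n_adults=50, n_children=80), seed=42)
pairs = compute_intakes(cohort.recalls, ctx, portion_db)
```

Running `python examples/02_simulate_and_ingest.py` prints:

```
generated 130 person-day recalls (1087 meal records)
reference utensils: bowl, cup, tumbler, plate, tablespoon, teaspoon, saucer
round-tripped 130 recalls through the two-table export
children: 80, of which breastfed yesterday: 65
example child declared 8 breastfeeds and has 8 breast-milk entries
```

i.e. a cohort of 130 synthetic participant-days whose export survives a
lossless write/read round trip, and in which every declared breastfeed
appears as a timed meal entry (the consistency the QC rule enforces).
`examples/04_nutrient_intakes.py` then screens a 9–11-mo child-day against
the RNI table and the breastfed energy ranges:

```
child C0001 (11 mo): 1129 kcal/day
  calcium_mg: 0.41 x RNI (400) -> below
  folate_ug: 4.45 x RNI (27.6) -> meets
  ...
energy classification: above (acceptable range 200-750 kcal for this age band)
```

The remaining examples cover FCT/recipe math (`01`), quality control and
field reports (`03`), and chrono-nutrition analytics (`05`).

## Command line

A thin CLI wraps the same functions:

```bash
dietrecall simulate --out-dir sim --seed 3 --n-adults 50 --n-children 80
dietrecall validate --demographics sim/demographics.csv --meals sim/meals.csv \
    --fct sim/fct.csv --portions sim/portions.csv
dietrecall compute  --demographics sim/demographics.csv --meals sim/meals.csv \
    --fct sim/fct.csv --portions sim/portions.csv --out-dir out
dietrecall analyze  --demographics sim/demographics.csv --meals sim/meals.csv \
    --fct sim/fct.csv --portions sim/portions.csv --out-dir out
```

## File dialects

* **FCT** (CSV/TSV, UTF-8): header `code, name, food_group, edible_fraction`
  plus nutrient columns named `energy_kcal, protein_g, animal_protein_g,
  fat_g, carb_g, fiber, calcium_mg, iron_mg, zinc_mg, vitA_ug_RE,
  folate_ug`; missing nutrient columns default to 0 with a warning. Values
  are per 100 g edible portion; the fiber unit is table metadata (default
  mg) and is never converted silently.
* **Demographics / meals**: see `dietrecall.ingest.DEMOG_COLUMNS` and
  `MEAL_COLUMNS`; times are 24-h `HH:MM`; free text is CSV-quoted; a
  column-mapping config supports alternative headers.
* **Portion DB** (CSV): `food_code_or_group, utensil, size, grams_per_unit,
  provenance`.
* **Recipes / code assignments**: human-editable YAML (see
  `RecipeRegistry.save` and `save_assignments`).

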