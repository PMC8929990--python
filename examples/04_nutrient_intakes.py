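"""Compute person-day nutrient intakes, screen RNI adequacy, and classify a
child's energy against the acceptable breastfed ranges.

Run:  python examples/04_nutrient_intakes.py
"""

import statistics

from dietrecall import (
    SimConfig,
    SubjectProfile,
    compute_intakes,
    energy_range_check,
    generate_cohort,
    rni_adequacy,
)

cohort, ctx, db, _ = generate_cohort(SimConfig(n_adults=100, n_children=200), seed=5)
pairs = compute_intakes(cohort.recalls, ctx, db)

adults = [(r, i) for r, i in pairs if r.demographics.cohort == "adult"]
by_sex = {"male": [], "female": []}
for r, i in adults:
    by_sex[r.demographics.sex].append(i.totals.energy_kcal)
for sex, vals in by_sex.items():
    print(f"median adult energy, {sex}: {statistics.median(vals):.0f} kcal "
          f"(n={len(vals)}) — synthetic diets, not a cohort estimate")

# RNI adequacy for one child-day (iron at 10% bioavailability, zinc moderate)
child, intake = next(
    (r, i) for r, i in pairs
    if r.demographics.cohort == "child" and 9 <= r.demographics.age_months <= 11
)
profile = SubjectProfile(
    age_months=child.demographics.age_months,
    sex=child.demographics.sex,
    tiers=(("folate_ug", "breast_milk_adjusted"),),
)
print(f"\nchild {child.demographics.participant_id} "
      f"({child.demographics.age_value:.0f} mo): "
      f"{intake.totals.energy_kcal:.0f} kcal/day")
for nutrient, adequacy in rni_adequacy(intake, profile).items():
    if adequacy is None:
        continue
    status = "meets" if adequacy.meets else "below"
    print(f"  {nutrient}: {adequacy.ratio:.2f} x RNI ({adequacy.rni_amount:g}) "
          f"-> {status}")

# acceptable energy range for a breastfed child of this age
breastfed = child.demographics.declared_bf_frequency > 0
cls, bounds = energy_range_check(
    intake.totals.energy_kcal, child.demographics.age_months, breastfed
)
if bounds:
    print(f"energy classification: {cls} (acceptable range "
          f"{bounds[0]:.0f}-{bounds[1]:.0f} kcal for this age band)")
else:
    print(f"energy classification: {cls}")
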