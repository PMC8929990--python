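"""Chrono-nutrition analytics: meal timing, energy by meal order, food away
from home, and food-frequency rankings.

Run:  python examples/05_meal_structure_analytics.py
"""

from dietrecall import (
    SimConfig,
    compute_intakes,
    energy_by_meal_order,
    fafh_summary,
    food_frequency_table,
    generate_cohort,
    location_share_table,
    timing_histogram,
)

cfg = SimConfig(n_adults=500, n_children=0)
cohort, ctx, db, _ = generate_cohort(cfg, seed=12)
adults = cohort.recalls
pairs = compute_intakes(adults, ctx, db)

# meal-timing histogram (60-min bins): counts of meal groups per clock hour
counts = timing_histogram(adults, 60)
peak_hours = sorted(range(24), key=lambda h: -counts[h])[:3]
print("busiest meal hours:",
      ", ".join(f"{h:02d}:00 ({counts[h]} meals)" for h in sorted(peak_hours)))

# share of daily energy by meal-order position, by sex
df = energy_by_meal_order(pairs, by=("sex",))
for sex in ("male", "female"):
    sub = df[df.sex == sex].sort_values("meal_order")
    shares = ", ".join(
        f"meal {int(r.meal_order)}: {100 * r.share:.0f}%"
        for r in sub.itertuples() if r.n >= 20
    )
    print(f"{sex} energy shares by meal order: {shares}")

# food away from home: median share of daily energy among those who ate out
s = fafh_summary(pairs)
for (sex,), median in s["median_share_by"].items():
    print(f"FAFH median energy share, {sex}: {100 * median:.0f}% "
          f"(n={s['n_by'][(sex,)]} away-eaters)")
print(location_share_table(adults).to_string(index=False,
                                             float_format=lambda v: f"{v:.1f}"))

# most frequently consumed foods (counts of meal records)
print("\ntop foods:")
for name, count in food_frequency_table(adults, top_n=5):
    print(f"  {count:4d}  {name}")
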