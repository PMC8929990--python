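# Methods

This note documents the models, conventions and numerical choices behind
`dietrecall`, in the order the pipeline applies them.

## The data model

A 24-h recall is exported as two delimited tables. The demographics table
has exactly one record per `(participant_id, recall_date)`: cohort, age
(months for children, years for adults), sex, the day's characterization
(typical / holiday-special / fasting / other), supplement use, and the
declared breastfeeding frequency. The meals table has one record per
consumed item: recorded entry order, clock time (`HH:MM`, stored as
minute-of-day; midnight is 0), one of eight consumption locations (home,
work, friend's house, roadside vendor, *mamalishe* — women food vendors —
restaurant, hotel, other), a food code or sentinel, free-text description,
an optional ingredient list, utensil/size/portion-count, a breast-milk
flag and free-text comments. Breast-milk entries carry timing and location
only — no portion report and never a nutrient estimate.

Unrecognized locations and day characterizations map to `other` with a
logged warning rather than failing, because field exports contain free-text
variants. Orphan meal rows (no matching demographics record) and duplicated
demographics keys are hard errors: they indicate a broken export, not noisy
data.

## Code resolution

Codes resolve by a deterministic cascade: (1) a direct hit in the primary
FCT; (2) the unknown-meal sentinel `9999` through the assignment table
(keyed by entry id, else by description) to a primary or secondary FCT
code; (3) the new-recipe sentinel `8888`, or an assignment naming a
registered recipe, to a recipe-derived pseudo-item; (4) otherwise
unresolved, with the attempted path recorded in an audit string. Matching
is by explicit assignment only — no fuzzy text matching — so the
assignment file is a reviewable artifact of the manual nutritionist
workflow it models. An `8888` entry with no recipe assigned is unresolved
with a distinct audit message, not an error: the day still computes, and
the per-day unresolved counter surfaces the gap. A supplemental FCT (for
tertiary-source ingredients such as octopus) participates in recipe
ingredient lookup only, never in direct code hits.

## Recipe nutrients per 100 g

For ingredient *i* with raw mass `g_i`, edible fraction `EP_i` and
per-100 g content `c_i`, the dish contributes `Σ g_i · EP_i · c_i / 100`,
renormalised to 100 g by the cooked weight `W` when recorded, else by the
raw mass total (a logged warning notes that moisture change is then
ignored). Retention factors are not applied. Two consequences are tested as
invariants: scaling all masses and the cooked weight by any `k > 0` leaves
the result unchanged, and without a cooked weight each component lies
inside the envelope of the EP-scaled ingredient components (weighted mean).

**Edible-fraction convention.** FCT values are per 100 g *edible portion*.
The edible fraction therefore multiplies as-served grams at intake time
(`intake = grams · EP / 100 × per-100 g`) and raw ingredient masses inside
recipes. Whether the original workflow applied EP before or after portion
conversion is not documented anywhere authoritative; this package fixes the
convention above and applies it consistently in both places.

## Portions

Grams consumed are `portion_count × grams_per_unit` of the best-matching
portion entry; food-specific keys beat food-group defaults, and the matched
entry travels with the result for audit. Densities are baked into the gram
estimates — the portion database ships grams, not volumes. A missing
mapping is an error by default, downgradeable to a logged warning with a
configurable fallback grams-per-unit, because field datasets contain gaps.

## Quality control

Rules are evaluated independently and return findings, never exceptions:

* `BF_MISMATCH` (error): breast-milk entry count ≠ declared frequency.
* `TWO_MORNINGS` (warning): the export carries clock times only, so a
  recall that spans two mornings (08:00 yesterday to 08:00 today) is
  detected heuristically — entry times in recorded order decrease
  somewhere, with a time before the morning cutoff (default 10:00) on both
  sides of the decrease. This is a heuristic and documented as such.
* `TIME_GAP` (warning): consecutive meal groups more than
  `max_gap_minutes` (default 360) apart, one finding per gap.
* `IMPLAUSIBLE_PORTION` (warning): converted grams above an age-class
  threshold. The published guidance is anecdotal (several cups of cooked
  rice for a 13-month-old), so the thresholds ship as editable config with
  deliberately generous defaults — 800 g per record for infants (< 24 mo),
  1500 g for children, 3000 g for adults — keyed by age class only. A
  food-state dimension (cooked vs dry, liquid vs solid) was considered and
  dropped: state-specific defaults would be invented precision.
* `UNAVAILABLE_FOOD` (warning): food code outside a user-supplied regional
  availability list; without a list the rule is off.

Reports (interview summary, daily field report, dietary profile) render
with stable sorts and fixed formatting so they can be diffed byte-for-byte
in tests.

## Meal grouping and analytics

A meal is any set of items consumed at the same time. Grouping is single
linkage over sorted times with a tolerance defaulting to 0 minutes (the
exact recorded time), since the instrument records simultaneity directly;
the tolerance is configurable for sloppier time entry. Meal order is the
per-day rank by time (1 = earliest) and is reported positionally rather
than as breakfast/lunch/dinner. Meal frequency counts groups, excluding
breast-milk-only groups when the "without breastfeeding" variant is
requested — a mixed group (food + breastfeed at one time) still counts as a
food meal.

Energy by meal order reports, per stratum (sex, weekday from the recall
date with a fixed English weekday mapping, cohort), the mean energy at each
order position and that position's share of the stratum's total energy;
shares sum to 1 within a stratum and `mean × n` summed over positions
recovers the stratum total exactly (a tested conservation law). The
food-away-from-home (FAFH) share is away-location energy over total daily
energy, per person-day; the population median is reported among persons
with at least one away-from-home food record, i.e. conditioned on eating
out at all, matching how such medians are quoted in the field. A zero-
energy day has an undefined share (`None`), never a division error.
Timing histograms use half-open clock-time bins whose width must divide
1440; totals equal the number of meal groups.

## RNI adequacy and energy ranges

Adequacy is `ratio = intake / RNI` with `meets = ratio ≥ 1`, matched on
nutrient, age band (in months), sex and bioavailability tier. The bundled
table is editable YAML holding standard FAO/WHO (2004) reference values —
iron at 10% bioavailability and zinc at moderate bioavailability, the tiers
appropriate to plant-based East African diets — plus a breast-milk-adjusted
folate RNI of 27.6 μg/d for 9–11 mo, stored as a constant because its
derivation is not published. A profile with no matching row yields
"not evaluable" rather than a guess.

Child energy classification uses the Dewey–Brown acceptable ranges for
breastfed children (100–600 / 200–750 / 500–1100 kcal for 6–8 / 9–11 /
12–23 mo) with **closed** intervals: an intake exactly on a bound is
"within". Ranges for non-breastfed children are not published alongside
these and are therefore not shipped; users can add `breastfed: false` rows
to the YAML, and absent rows yield "not evaluable".

## The synthetic-data generator

The generator exists so the pipeline can be tested end-to-end without
redistributing study data. It emulates structure, not outcome
distributions:

* **Cohorts.** Defaults of 312 adults (24.7% male, ages ~N(41, 9) y) and
  845 children in four age bands (0–5, 6–12, 13–18, 19–24 mo with weights
  83/360/262/140), breastfeeding prevalence falling 100% → 39% across
  bands and declared frequency medians 7/5/4/~3 among the breastfed; every
  declared breastfeed becomes a timed meal entry. Day characterization is
  ~97% "typical"; supplement use ~1%.
* **Meal timing.** Adult meal groups draw from morning/midday/evening
  modes at 09:00 / 13:30 / 20:30 (children 08:00 / 13:00 / 19:30, with
  tighter morning/evening spreads); extra meals land in a midday snack
  window. Where a planned day would contain an inter-meal gap above the
  generator's gap budget (330 min, under the QC default of 360), a small
  snack/beverage meal — afternoon tea — is inserted at the edge of the
  budget: realistic for the setting, and it keeps fault-free cohorts
  exactly clean so fault-recovery tests can demand multiset equality. A
  consequence is that the generated adult meal-frequency median sits at
  3–4 rather than 3.
* **Food away from home.** Eating out is person-level (propensity 0.6 for
  men, 0.2 for women); an away-eater's earliest meals are assigned away
  locations (eating out happens at morning and lunch meals) and the away
  portion counts are rescaled so the person's away energy share hits a
  target drawn around 0.54 (men) / 0.39 (women), sd 0.05. The rescaling is
  exact when the scale factor stays inside its plausibility clip, so the
  population median share among away-eaters recovers the configured target
  — the statistic is conditioned on eating out, which a per-meal
  propensity alone would not control.
* **Portions and foods.** A mock FCT spans 10 food groups of named East
  African foods with group-typical nutrient ranges (animal-source protein
  is a fraction of total protein only in animal-source groups, so the
  invariant holds by construction) and edible fractions below 1 for
  fruits/tubers/fish. The portion database covers every group × utensil ×
  size plus one food-specific override per group to exercise precedence.
  Child portion draws shrink with age down from the adult baseline so
  child-day energies grow from a few hundred kcal in infancy to ~1000+
  kcal by two years.
* **Fault injection.** Requested rules are planted in disjoint recalls:
  breastfeeding mismatch increments the declared frequency; two-mornings
  appends a next-morning entry as the last recorded index; time-gap remaps
  the day's group times onto a pattern with exactly one 390-min gap;
  implausible-portion sets one record to 15 large plates. The ground truth
  is returned so tests can require the validator's finding multiset to
  equal it exactly.

What passing tests on synthetic data do **not** show: the generator does
not reproduce real nutrient-intake distributions, inter-food correlations
within meals, recall/reporting error, or seasonal and regional menu
variation. Pipeline correctness (arithmetic, conservation, exclusion,
grouping, QC detection) transfers to real exports in the documented
dialects; population-level numbers printed by the examples are properties
of the generator, not estimates.

## Numerical and determinism choices

All randomness flows from `numpy.random.default_rng` seeded explicitly;
identical seeds give byte-identical exports. Floats are serialized with
`repr` so write/read round trips are exact, and round-trip tests assert
byte equality of re-serialized files. Nutrient vectors validate
non-negativity and animal ≤ total protein with a 1e-9 relative slack to
absorb float summation. Vector comparisons in tests use relative
tolerances of 1e-9 or tighter; the oracle-equivalence check demands
agreement with an independent brute-force recomputation to 1e-9 relative.
Tie-breaks are deterministic everywhere: grouping ties by entry index,
food-frequency ties alphabetically, report orderings by time then index.

Problem sizes in the test suite and acceptance script (cohorts of 100–500
person-days, 1000 random recipes) were chosen as the smallest sizes at
which the stochastic recovery checks are stable; everything runs in
seconds on one CPU.

## Known limitations

* No usual-intake modeling, within-person variance deconvolution, or
  supplement nutrient contributions (supplement use is carried as a flag).
* No statistical testing between strata; summaries are descriptive.
* The two-mornings rule is a heuristic over clock times; a recall tool
  exporting full timestamps would make it exact.
* Fiber units are carried as metadata, never converted; mixing tables with
  different fiber units is the user's responsibility.
* The breast-milk-adjusted folate RNI is a stored constant, not derived.
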