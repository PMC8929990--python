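"""Seeded generators for mock food-composition data and synthetic cohorts.

No study data are redistributed with this package, so tests and examples run
on synthetic cohorts that emulate the two study populations the pipeline was
built for:

* an **adult** peri-urban cohort (default n = 312, about a quarter male)
  with ~3-4 meals a day at morning / midday / evening modes, and strongly
  gendered food-away-from-home (FAFH) behaviour — most men but few women eat
  some meals out, and eating-out men consume a larger share of their daily
  energy away from home;
* a **child** rural cohort (default n = 845, ages 0-24 mo) with age-graded
  breastfeeding (declared frequency falling from a median of 7 under 6 mo to
  ~0 by 19-24 mo) and meal frequency including breastfeeding falling from ~9
  to ~6, where every breastfeed is recorded as a timed meal entry.

The generator emits exactly the two-table export the ingest module reads.
Without fault injection the cohorts are clean by construction: breast-milk
entry counts equal declared frequencies, inter-meal gaps stay under the QC
threshold (a small snack/beverage meal — afternoon tea — is inserted to
bridge what would otherwise be an implausible gap), portions stay under the
plausibility thresholds, and entry indices follow clock time.  With fault
injection, faults are planted in disjoint recalls and the ground-truth list
is returned for exact recovery checks.

A per-person target FAFH energy share is realised by scaling the portion
counts of away-from-home meals, so the population median share among
away-eaters recovers the configured value.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fct import FCTable, FctContext, FoodItem
from .ingest import (
    DemographicRecord,
    MealEntry,
    PersonDayRecall,
    demog_to_row,
    entry_to_row,
    write_normalized,
    DEMOG_COLUMNS,
    MEAL_COLUMNS,
)
from .nutrivec import NutrientVector
from .portions import PortionDatabase, PortionEntry, UtensilRegistry
from .quality import (
    RULE_BF_MISMATCH,
    RULE_IMPLAUSIBLE_PORTION,
    RULE_TIME_GAP,
    RULE_TWO_MORNINGS,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChildBand:
    """Age band of the child cohort with its breastfeeding structure."""

    lo_mo: int
    hi_mo: int
    weight: float  # share of the cohort
    bf_prob: float  # probability breastfed in the previous 24 h
    bf_freq_median: int  # declared breastfeeding frequency when breastfed
    food_meals_median: int  # non-breast-milk meal groups per day


def _default_child_bands() -> tuple[ChildBand, ...]:
    return (
        ChildBand(0, 5, 83 / 845, 1.00, 7, 2),
        ChildBand(6, 12, 360 / 845, 0.975, 5, 4),
        ChildBand(13, 18, 262 / 845, 0.779, 4, 4),
        ChildBand(19, 24, 140 / 845, 0.386, 3, 5),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohorts (defaults mirror the
    published cohort structure; values are defaults, not estimates)."""

    n_adults: int = 312
    n_children: int = 845
    male_frac_adults: float = 0.247
    # meal-group count distribution for adults (median 3)
    adult_meal_counts: tuple[tuple[int, float], ...] = (
        (2, 0.15), (3, 0.60), (4, 0.20), (5, 0.05)
    )
    # entries per meal group
    entries_per_meal: tuple[tuple[int, float], ...] = ((1, 0.45), (2, 0.40), (3, 0.15))
    # (mode minute-of-day, sd) for morning / midday / evening meals
    adult_time_modes: tuple[tuple[int, int], ...] = ((540, 40), (810, 55), (1230, 40))
    child_time_modes: tuple[tuple[int, int], ...] = ((480, 30), (780, 70), (1170, 30))
    snack_window: tuple[int, int] = (600, 1100)
    # clean cohorts never exceed this inter-meal gap (kept under the QC
    # default of 360 so fault recovery is exact)
    max_gap_minutes: int = 330
    # person-level probability of eating any meal away from home
    fafh_propensity: tuple[tuple[str, float], ...] = (("male", 0.6), ("female", 0.2))
    # target away-from-home share of daily energy for away-eaters
    fafh_energy_share: tuple[tuple[str, float], ...] = (("male", 0.54), ("female", 0.39))
    fafh_share_sd: float = 0.05
    away_locations: tuple[tuple[str, float], ...] = (
        ("restaurant", 0.28),
        ("mamalishe", 0.22),
        ("work", 0.18),
        ("roadside_vendor", 0.14),
        ("hotel", 0.06),
        ("friend_house", 0.06),
        ("other", 0.06),
    )
    day_characters: tuple[tuple[str, float], ...] = (
        ("typical", 0.97), ("holiday_special", 0.015), ("fasting", 0.01), ("other", 0.005)
    )
    supplement_rate: float = 0.01
    child_bands: tuple[ChildBand, ...] = field(default_factory=_default_child_bands)
    # fraction of eligible recalls to plant each fault into (disjoint sets)
    fault_rates: tuple[tuple[str, float], ...] = ()
    base_date: str = "2019-03-11"  # a Monday; recall dates cycle over one week


def _choice(rng: np.random.Generator, pairs) -> object:
    keys = [k for k, _ in pairs]
    probs = np.array([p for _, p in pairs], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _lookup(pairs, key):
    for k, v in pairs:
        if k == key:
            return v
    raise KeyError(key)


# ---------------------------------------------------------------------------
# mock food-composition and portion data
# ---------------------------------------------------------------------------

# name lists and per-100 g nutrient ranges per food group; animal-source
# protein is a fraction of total protein only for animal-source groups
_GROUPS: dict[str, dict] = {
    "cereals": dict(
        names=[
            "maize ugali (stiff porridge)",
            "rice boiled with oil",
            "mixed flour porridge with sugar",
            "maize porridge with sugar",
            "chapati with oil",
            "bread, white",
            "sorghum porridge",
        ],
        energy=(110, 360), protein=(2.0, 9.0), animal_frac=(0.0, 0.0),
        fat=(0.5, 9.0), carb=(20, 75), fiber=(0.5, 4.0), ca=(5, 30),
        fe=(0.3, 2.5), zn=(0.3, 2.0), vita=(0, 10), folate=(5, 40),
        ef=(1.0, 1.0), utensils=("plate", "bowl"),
    ),
    "legumes": dict(
        names=[
            "beans, kidney, mature, boiled",
            "kidney bean relish with oil",
            "cowpea relish",
            "pigeon pea stew",
        ],
        energy=(90, 160), protein=(5.0, 10.0), animal_frac=(0.0, 0.0),
        fat=(0.5, 6.0), carb=(12, 25), fiber=(3.0, 8.0), ca=(20, 60),
        fe=(1.5, 3.5), zn=(0.8, 1.8), vita=(0, 5), folate=(60, 180),
        ef=(1.0, 1.0), utensils=("bowl", "plate", "tablespoon"),
    ),
    "vegetables": dict(
        names=[
            "green leaf relish without oil",
            "amaranth leaves, boiled, drained",
            "sweet potato leaf relish",
            "cabbage, onion salad",
            "okra stew",
        ],
        energy=(20, 90), protein=(1.0, 4.5), animal_frac=(0.0, 0.0),
        fat=(0.1, 5.0), carb=(3, 12), fiber=(1.5, 5.0), ca=(40, 250),
        fe=(0.8, 4.0), zn=(0.2, 1.0), vita=(50, 500), folate=(30, 120),
        ef=(0.85, 1.0), utensils=("bowl", "saucer", "tablespoon"),
    ),
    "fruits": dict(
        names=["mango, ripe, fresh", "banana, ripe", "papaya, ripe", "watermelon slice", "orange"],
        energy=(30, 100), protein=(0.3, 1.5), animal_frac=(0.0, 0.0),
        fat=(0.1, 0.5), carb=(7, 25), fiber=(0.8, 3.0), ca=(5, 30),
        fe=(0.1, 0.8), zn=(0.05, 0.3), vita=(5, 120), folate=(5, 40),
        ef=(0.55, 0.85), utensils=("plate", "saucer"),
    ),
    "meat_fish": dict(
        names=[
            "beef relish with oil",
            "fish relish with oil",
            "small dried fish with tomatoes and oil",
            "fish, fried",
            "fish, fresh, stew",
            "beef broth with oil",
            "chicken stew",
        ],
        energy=(120, 280), protein=(12.0, 26.0), animal_frac=(0.85, 1.0),
        fat=(4.0, 18.0), carb=(0, 6), fiber=(0.0, 0.5), ca=(10, 400),
        fe=(0.8, 4.0), zn=(0.8, 4.5), vita=(0, 60), folate=(2, 20),
        ef=(0.75, 1.0), utensils=("bowl", "plate", "saucer"),
    ),
    "dairy": dict(
        names=["milk, whole, 3.25% milk fat", "yogurt, plain, whole milk", "fermented milk"],
        energy=(55, 100), protein=(3.0, 5.5), animal_frac=(1.0, 1.0),
        fat=(3.0, 5.0), carb=(4, 8), fiber=(0.0, 0.0), ca=(100, 180),
        fe=(0.02, 0.2), zn=(0.3, 0.6), vita=(20, 60), folate=(4, 12),
        ef=(1.0, 1.0), utensils=("cup", "tumbler"),
    ),
    "fats_oils": dict(
        names=["sunflower oil", "coconut milk, thick", "margarine"],
        energy=(250, 884), protein=(0.0, 2.5), animal_frac=(0.0, 0.0),
        fat=(25, 100), carb=(0, 6), fiber=(0.0, 0.0), ca=(0, 20),
        fe=(0.0, 1.0), zn=(0.0, 0.5), vita=(0, 80), folate=(0, 5),
        ef=(1.0, 1.0), utensils=("tablespoon", "teaspoon"),
    ),
    "beverages": dict(
        names=[
            "tea without milk, with sugar",
            "tea with milk and sugar",
            "carbonated beverage, cola",
            "mango juice",
            "millet bun tea",
        ],
        energy=(15, 60), protein=(0.0, 1.5), animal_frac=(0.0, 0.6),
        fat=(0.0, 1.5), carb=(3, 14), fiber=(0.0, 0.2), ca=(2, 40),
        fe=(0.0, 0.3), zn=(0.0, 0.2), vita=(0, 15), folate=(0, 8),
        ef=(1.0, 1.0), utensils=("cup", "tumbler"),
    ),
    "snacks": dict(
        names=["donut, African", "potato chips, fried", "samosa with potatoes", "boiled maize cob"],
        energy=(250, 450), protein=(3.0, 7.0), animal_frac=(0.0, 0.0),
        fat=(10, 25), carb=(30, 55), fiber=(1.0, 4.0), ca=(10, 40),
        fe=(0.5, 2.0), zn=(0.3, 1.0), vita=(0, 10), folate=(10, 40),
        ef=(1.0, 1.0), utensils=("saucer", "plate"),
    ),
    "tubers": dict(
        names=["cassava, fried", "sweet potato, boiled", "cooking banana, boiled", "irish potato stew"],
        energy=(80, 200), protein=(0.8, 2.5), animal_frac=(0.0, 0.0),
        fat=(0.1, 8.0), carb=(18, 40), fiber=(1.0, 4.0), ca=(10, 50),
        fe=(0.3, 1.5), zn=(0.2, 0.8), vita=(0, 300), folate=(10, 40),
        ef=(0.8, 1.0), utensils=("plate", "bowl"),
    ),
}

# grams of one medium unit per utensil; size classes scale by 0.75 / 1 / 1.25
_UTENSIL_GRAMS = {
    "teaspoon": 5.0,
    "tablespoon": 15.0,
    "saucer": 80.0,
    "cup": 240.0,
    "tumbler": 300.0,
    "bowl": 350.0,
    "plate": 400.0,
}
_SIZE_FACTORS = {"small": 0.75, "medium": 1.0, "large": 1.25}

# which meal groups a food group is drawn for, with weights (adult, child)
_GROUP_WEIGHTS_ADULT = (
    ("cereals", 0.28), ("meat_fish", 0.15), ("beverages", 0.14), ("legumes", 0.09),
    ("vegetables", 0.11), ("tubers", 0.07), ("snacks", 0.07), ("fruits", 0.05),
    ("dairy", 0.02), ("fats_oils", 0.02),
)
_GROUP_WEIGHTS_CHILD = (
    ("cereals", 0.40), ("dairy", 0.14), ("meat_fish", 0.12), ("vegetables", 0.09),
    ("fruits", 0.08), ("tubers", 0.07), ("legumes", 0.06), ("beverages", 0.03),
    ("snacks", 0.01),
)


def generate_fct(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[FCTable, PortionDatabase, UtensilRegistry]:
    """Mock food-composition table, portion-size database and utensil
    registry.

    The table spans 10 food groups with nonnegative nutrient vectors
    (animal-source protein never exceeds total protein by construction) and
    edible fractions in (0, 1].  The portion database carries group defaults
    for every utensil/size so every generated food has a resolvable portion
    key, plus a food-specific override per group (to exercise lookup
    precedence).
    """
    del config  # ranges are fixed; the signature mirrors generate_recalls
    rng = np.random.default_rng(seed)
    table = FCTable(source_label="primary", fiber_unit="mg")
    code_n = 1
    for group in sorted(_GROUPS):
        spec = _GROUPS[group]
        for name in spec["names"]:
            protein = rng.uniform(*spec["protein"])
            vec = NutrientVector(
                energy_kcal=round(rng.uniform(*spec["energy"]), 1),
                protein_g=round(protein, 2),
                animal_protein_g=round(protein * rng.uniform(*spec["animal_frac"]), 2),
                fat_g=round(rng.uniform(*spec["fat"]), 2),
                carb_g=round(rng.uniform(*spec["carb"]), 1),
                fiber=round(rng.uniform(*spec["fiber"]), 2),
                calcium_mg=round(rng.uniform(*spec["ca"]), 1),
                iron_mg=round(rng.uniform(*spec["fe"]), 2),
                zinc_mg=round(rng.uniform(*spec["zn"]), 2),
                vitA_ug_RE=round(rng.uniform(*spec["vita"]), 1),
                folate_ug=round(rng.uniform(*spec["folate"]), 1),
            )
            table.add(
                FoodItem(
                    code=f"TZ{code_n:03d}",
                    name=name,
                    food_group=group,
                    per100g=vec,
                    edible_fraction=round(rng.uniform(*spec["ef"]), 2),
                )
            )
            code_n += 1

    db = PortionDatabase()
    for group in sorted(_GROUPS):
        for utensil, base in sorted(_UTENSIL_GRAMS.items()):
            for size, factor in sorted(_SIZE_FACTORS.items()):
                db.add(
                    PortionEntry(
                        key=group,
                        utensil=utensil,
                        size=size,
                        grams_per_unit=round(base * factor, 1),
                        provenance="synthetic group default",
                    )
                )
    # one food-specific override per group: first food, first allowed utensil
    for group in sorted(_GROUPS):
        first_item = next(
            it for it in table.items.values() if it.food_group == group
        )
        utensil = _GROUPS[group]["utensils"][0]
        db.add(
            PortionEntry(
                key=first_item.code,
                utensil=utensil,
                size="medium",
                grams_per_unit=round(_UTENSIL_GRAMS[utensil] * 1.1, 1),
                provenance="synthetic food-specific estimate",
            )
        )
    return table, db, UtensilRegistry()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class InjectedFault:
    participant_id: str
    recall_date: str
    rule_id: str


@dataclass
class SyntheticCohort:
    """Generated recalls, the two-table export, and the fault ground truth."""

    recalls: list[PersonDayRecall]
    faults: list[InjectedFault]
    seed: int

    @property
    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame(
            [demog_to_row(r.demographics) for r in self.recalls],
            columns=list(DEMOG_COLUMNS),
        )

    @property
    def meals(self) -> pd.DataFrame:
        rows = [
            entry_to_row(e)
            for r in self.recalls
            for e in sorted(r.entries, key=lambda e: e.entry_index)
        ]
        return pd.DataFrame(rows, columns=list(MEAL_COLUMNS))

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        return write_normalized(
            self.recalls,
            out_dir / "demographics.csv",
            out_dir / "meals.csv",
        )


def _plan_times(
    rng: np.random.Generator,
    n_food: int,
    modes: tuple[tuple[int, int], ...],
    snack_window: tuple[int, int],
    bf_times: list[int],
    max_gap: int,
) -> tuple[list[int], list[int], list[tuple[int, str]]]:
    """Plan distinct meal-group times for one day.

    Returns (food_times, bf_times, snack_times_with_kind) where snack groups
    were inserted to bridge gaps larger than ``max_gap``.  All times are
    distinct minutes; consecutive gaps over the full set never exceed
    ``max_gap``.
    """
    morning, midday, evening = modes
    picks: list[int] = []
    if n_food >= 1:
        picks.append(int(np.clip(rng.normal(*morning), 400, 585)))
    if n_food >= 2:
        picks.append(int(np.clip(rng.normal(*evening), 1050, 1380)))
    if n_food >= 3:
        picks.append(int(np.clip(rng.normal(*midday), 640, 1000)))
    for _ in range(max(0, n_food - 3)):
        picks.append(int(rng.uniform(*snack_window)))

    used: set[int] = set()

    def _place(t: int) -> int:
        while t in used:
            t += 7
        used.add(t)
        return t

    food_times = sorted(_place(t) for t in picks)
    bf_placed = sorted(_place(int(t)) for t in bf_times)

    # bridge gaps with snack/beverage groups (afternoon-tea style)
    snacks: list[tuple[int, str]] = []
    all_times = sorted(used)
    changed = True
    while changed:
        changed = False
        for prev, cur in zip(all_times, all_times[1:]):
            if cur - prev > max_gap:
                t = _place(prev + max_gap - 30)
                snacks.append((t, "beverages" if rng.random() < 0.6 else "snacks"))
                all_times = sorted(used)
                changed = True
                break
    return food_times, bf_placed, snacks


def _food_entries_for_group(
    rng: np.random.Generator,
    cfg: SimConfig,
    fct: FCTable,
    time: int,
    location: str,
    group_weights,
    n_entries: int,
    max_portion: float,
    items_by_group: dict[str, list[FoodItem]],
    *,
    size_probs: tuple[float, float, float] = (0.3, 0.5, 0.2),
    portion_mu: float = 0.0,
    min_portion: float = 0.25,
) -> list[dict]:
    out = []
    for _ in range(n_entries):
        group = _choice(rng, group_weights)
        item = items_by_group[group][rng.integers(len(items_by_group[group]))]
        utensil = _GROUPS[group]["utensils"][
            rng.integers(len(_GROUPS[group]["utensils"]))
        ]
        size = ("small", "medium", "large")[
            rng.choice(3, p=np.array(size_probs) / sum(size_probs))
        ]
        portion = float(
            np.clip(round(rng.lognormal(portion_mu, 0.35), 2), min_portion, max_portion)
        )
        out.append(
            dict(
                time=time,
                location=location,
                item=item,
                utensil=utensil,
                size=size,
                portion=portion,
            )
        )
    return out


def _entry_energy(draft: dict, db: PortionDatabase) -> float:
    item: FoodItem = draft["item"]
    entry, _level = db.lookup(item.code, draft["utensil"], draft["size"], item.food_group)
    grams = draft["portion"] * entry.grams_per_unit
    return grams * item.edible_fraction / 100.0 * item.per100g.energy_kcal


def _materialize(
    demog: DemographicRecord, drafts: list[dict], bf_times: list[int]
) -> PersonDayRecall:
    """Turn entry drafts + breast-milk times into an indexed recall (entry
    indices follow clock time)."""
    records: list[tuple[int, int, dict | None]] = []
    for d in drafts:
        records.append((d["time"], 0, d))
    for t in bf_times:
        records.append((t, 1, None))
    records.sort(key=lambda r: (r[0], r[1]))
    entries = []
    for idx, (time, _kind, d) in enumerate(records, start=1):
        if d is None:
            entries.append(
                MealEntry(
                    participant_id=demog.participant_id,
                    recall_date=demog.recall_date,
                    entry_index=idx,
                    clock_time=time,
                    location="home",
                    food_code="",
                    description="breast milk",
                    ingredients=None,
                    utensil="",
                    utensil_size="",
                    portion_count=None,
                    is_breastmilk=True,
                )
            )
        else:
            item: FoodItem = d["item"]
            entries.append(
                MealEntry(
                    participant_id=demog.participant_id,
                    recall_date=demog.recall_date,
                    entry_index=idx,
                    clock_time=time,
                    location=d["location"],
                    food_code=item.code,
                    description=item.name,
                    ingredients=d.get("ingredients"),
                    utensil=d["utensil"],
                    utensil_size=d["size"],
                    portion_count=d["portion"],
                    is_breastmilk=False,
                )
            )
    return PersonDayRecall(demographics=demog, entries=entries)


def _generate_adult(
    rng: np.random.Generator,
    cfg: SimConfig,
    i: int,
    fct: FCTable,
    db: PortionDatabase,
    items_by_group: dict[str, list[FoodItem]],
    base_date: dt.date,
) -> PersonDayRecall:
    sex = "male" if rng.random() < cfg.male_frac_adults else "female"
    demog = DemographicRecord(
        participant_id=f"A{i:04d}",
        recall_date=base_date + dt.timedelta(days=int(i % 7)),
        cohort="adult",
        age_value=float(int(np.clip(rng.normal(41, 9), 19, 70))),
        age_unit="years",
        sex=sex,
        day_character=_choice(rng, cfg.day_characters),
        supplement_use=bool(rng.random() < cfg.supplement_rate),
        declared_bf_frequency=0,
    )
    n_food = _choice(rng, cfg.adult_meal_counts)
    food_times, _bf, snacks = _plan_times(
        rng, n_food, cfg.adult_time_modes, cfg.snack_window, [], cfg.max_gap_minutes
    )

    drafts: list[dict] = []
    for t in food_times:
        n_entries = _choice(rng, cfg.entries_per_meal)
        drafts.extend(
            _food_entries_for_group(
                rng, cfg, fct, t, "home", _GROUP_WEIGHTS_ADULT, n_entries, 3.0,
                items_by_group,
            )
        )
    for t, group in snacks:
        item = items_by_group[group][rng.integers(len(items_by_group[group]))]
        utensil = _GROUPS[group]["utensils"][0]
        drafts.append(
            dict(time=t, location="home", item=item, utensil=utensil,
                 size="medium", portion=1.0)
        )

    # food-away-from-home: away-eaters get their earliest meals assigned to
    # away locations, then away portion counts are scaled so the away share
    # of daily energy hits the person's target share
    if rng.random() < _lookup(cfg.fafh_propensity, sex):
        target = float(
            np.clip(
                rng.normal(_lookup(cfg.fafh_energy_share, sex), cfg.fafh_share_sd),
                0.05,
                0.9,
            )
        )
        times_sorted = sorted({d["time"] for d in drafts})
        n_groups = len(times_sorted)
        n_away = int(np.clip(round(target * n_groups), 1, max(1, n_groups - 1)))
        away_times = set(times_sorted[:n_away])  # mornings first
        away_loc = {t: _choice(rng, cfg.away_locations) for t in away_times}
        for d in drafts:
            if d["time"] in away_times:
                d["location"] = away_loc[d["time"]]
        away_e = sum(_entry_energy(d, db) for d in drafts if d["time"] in away_times)
        home_e = sum(_entry_energy(d, db) for d in drafts if d["time"] not in away_times)
        if away_e > 0 and home_e > 0:
            f = float(np.clip(target * home_e / ((1 - target) * away_e), 0.3, 2.2))
            for d in drafts:
                if d["time"] in away_times:
                    d["portion"] = round(min(d["portion"] * f, 5.5), 4)

    # occasional free-text ingredient list (round-trip realism)
    if rng.random() < 0.05 and drafts:
        d = drafts[int(rng.integers(len(drafts)))]
        d["ingredients"] = (("maize flour", "TZ001"), ("water, salt", ""))

    return _materialize(demog, drafts, [])


def _generate_child(
    rng: np.random.Generator,
    cfg: SimConfig,
    i: int,
    fct: FCTable,
    db: PortionDatabase,
    items_by_group: dict[str, list[FoodItem]],
    base_date: dt.date,
) -> PersonDayRecall:
    bands = cfg.child_bands
    band = bands[
        rng.choice(len(bands), p=np.array([b.weight for b in bands]) / sum(b.weight for b in bands))
    ]
    breastfed = rng.random() < band.bf_prob
    declared = (
        int(np.clip(round(rng.normal(band.bf_freq_median, 1.5)), 1, 12))
        if breastfed
        else 0
    )
    demog = DemographicRecord(
        participant_id=f"C{i:04d}",
        recall_date=base_date + dt.timedelta(days=int(i % 7)),
        cohort="child",
        age_value=float(int(rng.integers(band.lo_mo, band.hi_mo + 1))),
        age_unit="months",
        sex="female" if rng.random() < 0.5 else "male",
        day_character=_choice(rng, cfg.day_characters),
        supplement_use=bool(rng.random() < cfg.supplement_rate),
        declared_bf_frequency=declared,
    )
    n_food = int(np.clip(band.food_meals_median + rng.integers(-1, 2), 1, 7))
    bf_times = [int(rng.uniform(330, 1290)) for _ in range(declared)]
    food_times, bf_placed, snacks = _plan_times(
        rng, n_food, cfg.child_time_modes, cfg.snack_window, bf_times, cfg.max_gap_minutes
    )
    drafts: list[dict] = []
    for t in food_times:
        n_entries = _choice(rng, (((1, 0.6), (2, 0.4))))
        location = "home" if rng.random() < 0.95 else "other"
        drafts.extend(
            _food_entries_for_group(
                rng, cfg, fct, t, location, _GROUP_WEIGHTS_CHILD, n_entries, 0.8,
                items_by_group,
                # small servings: infants and toddlers eat fractions of the
                # reference utensils, growing with age
                size_probs=(0.7, 0.3, 0.0),
                portion_mu=-1.3 + 0.03 * demog.age_months,
                min_portion=0.1,
            )
        )
    for t, group in snacks:
        item = items_by_group[group][rng.integers(len(items_by_group[group]))]
        drafts.append(
            dict(time=t, location="home", item=item,
                 utensil=_GROUPS[group]["utensils"][0], size="small", portion=0.25)
        )
    return _materialize(demog, drafts, bf_placed)


# -- fault injection --------------------------------------------------------


def _inject_bf_mismatch(recall: PersonDayRecall, rng) -> None:
    recall.demographics.declared_bf_frequency += 1


def _inject_two_mornings(
    recall: PersonDayRecall, rng, fct: FCTable, items_by_group
) -> None:
    # append (as the last recorded entry) a food eaten the *next* morning,
    # earlier on the clock than everything before it
    first_time = min(e.clock_time for e in recall.entries)
    new_time = max(first_time - 150, 240)
    item = items_by_group["beverages"][0]
    recall.entries.append(
        MealEntry(
            participant_id=recall.demographics.participant_id,
            recall_date=recall.demographics.recall_date,
            entry_index=max(e.entry_index for e in recall.entries) + 1,
            clock_time=new_time,
            location="home",
            food_code=item.code,
            description=item.name,
            ingredients=None,
            utensil="cup",
            utensil_size="medium",
            portion_count=1.0,
            is_breastmilk=False,
        )
    )


def _inject_time_gap(recall: PersonDayRecall, rng) -> None:
    # remap group times onto a pattern with exactly one 390-min gap
    old_times = sorted({e.clock_time for e in recall.entries})
    m = len(old_times)
    new_times = [420, 480]
    if m > 2:
        # remaining groups evenly spaced in [870, 1400]: one gap of 390,
        # the rest well under the QC threshold
        step = max(1, int((1400 - 870) / max(1, m - 3))) if m > 3 else 0
        t = 870
        while len(new_times) < m:
            new_times.append(t)
            t += min(step or 55, 55)
    mapping = dict(zip(old_times, new_times[: len(old_times)]))
    for e in recall.entries:
        e.clock_time = mapping[e.clock_time]
    # keep entry indices consistent with the (unchanged) time order
    recall.entries.sort(key=lambda e: (e.clock_time, e.entry_index))
    for idx, e in enumerate(recall.entries, start=1):
        e.entry_index = idx


def _inject_implausible_portion(recall: PersonDayRecall, rng) -> None:
    foods = [e for e in recall.entries if not e.is_breastmilk]
    e = foods[int(rng.integers(len(foods)))]
    e.utensil, e.utensil_size, e.portion_count = "plate", "large", 15.0


def generate_recalls(
    config: SimConfig,
    seed: int,
    fct: FCTable,
    portion_db: PortionDatabase,
) -> SyntheticCohort:
    """Generate the synthetic two-table export.

    Without fault injection every recall is clean: the QC validator returns
    no findings, and children's breast-milk entry counts equal their declared
    frequencies.  With ``config.fault_rates`` set, faults are planted in
    disjoint recalls and the ground-truth list is returned.
    """
    rng = np.random.default_rng(seed)
    base_date = dt.date.fromisoformat(config.base_date)
    items_by_group: dict[str, list[FoodItem]] = {}
    for it in fct.items.values():
        items_by_group.setdefault(it.food_group, []).append(it)
    for group in items_by_group:
        items_by_group[group].sort(key=lambda it: it.code)

    recalls: list[PersonDayRecall] = []
    for i in range(config.n_adults):
        recalls.append(
            _generate_adult(rng, config, i, fct, portion_db, items_by_group, base_date)
        )
    for i in range(config.n_children):
        recalls.append(
            _generate_child(rng, config, i, fct, portion_db, items_by_group, base_date)
        )

    faults: list[InjectedFault] = []
    if config.fault_rates:
        taken: set[int] = set()
        n = len(recalls)
        for rule_id, rate in config.fault_rates:
            count = int(round(rate * n))
            if rule_id == RULE_BF_MISMATCH:
                eligible = [
                    j for j in range(n)
                    if j not in taken and recalls[j].demographics.declared_bf_frequency >= 1
                ]
            elif rule_id == RULE_TIME_GAP:
                eligible = [
                    j for j in range(n)
                    if j not in taken and len({e.clock_time for e in recalls[j].entries}) >= 3
                ]
            else:
                eligible = [
                    j for j in range(n)
                    if j not in taken
                    and any(not e.is_breastmilk for e in recalls[j].entries)
                ]
            chosen = rng.choice(len(eligible), size=min(count, len(eligible)), replace=False)
            for k in sorted(int(c) for c in chosen):
                j = eligible[k]
                taken.add(j)
                r = recalls[j]
                if rule_id == RULE_BF_MISMATCH:
                    _inject_bf_mismatch(r, rng)
                elif rule_id == RULE_TWO_MORNINGS:
                    _inject_two_mornings(r, rng, fct, items_by_group)
                elif rule_id == RULE_TIME_GAP:
                    _inject_time_gap(r, rng)
                elif rule_id == RULE_IMPLAUSIBLE_PORTION:
                    _inject_implausible_portion(r, rng)
                else:
                    raise ValueError(f"unsupported fault rule {rule_id!r}")
                faults.append(
                    InjectedFault(
                        participant_id=r.demographics.participant_id,
                        recall_date=r.demographics.recall_date.isoformat(),
                        rule_id=rule_id,
                    )
                )
    return SyntheticCohort(recalls=recalls, faults=faults, seed=seed)


def generate_cohort(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[SyntheticCohort, FctContext, PortionDatabase, UtensilRegistry]:
    """One-call convenience: mock FCT + portion DB + cohort + resolution
    context, all from one seed."""
    config = config or SimConfig()
    fct, db, registry = generate_fct(config, seed)
    cohort = generate_recalls(config, seed + 1, fct, db)
    return cohort, FctContext(primary=fct), db, registry
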