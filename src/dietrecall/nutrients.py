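"""Per-meal and per-person-day nutrient computation and adequacy screening.

The core arithmetic is deliberately simple: the grams consumed for each meal
record (portion count x grams per serving unit) are multiplied by the
resolved food's per-100 g nutrient content, with the food's edible fraction
applied to the as-served grams.  Breast-milk records contribute timing and
frequency but no nutrients; unresolved codes contribute zero and are counted
per day rather than failing the whole day.

Daily totals can be screened against a Recommended Nutrient Intake (RNI)
table (ratio of intake to the age/sex/bioavailability-matched RNI) and, for
young children, against acceptable energy-intake ranges for breastfed
children.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .chrono import meal_frequency
from .fct import FctContext, ResolvedFood, SOURCE_UNRESOLVED
from .ingest import MealEntry, PersonDayRecall
from .nutrivec import NutrientVector, vector_sum
from .portions import PortionDatabase, amount_consumed_g

logger = logging.getLogger(__name__)

EXCLUDED_BREAST_MILK = "breast_milk"
EXCLUDED_UNRESOLVED = "unresolved"


@dataclass(frozen=True, slots=True)
class MealIntake:
    """Nutrients for one meal record (zero vector when excluded)."""

    entry_index: int
    description: str
    grams: float
    nutrients: NutrientVector
    source: str
    excluded: bool = False
    exclusion_reason: str | None = None
    portion_audit: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.nutrients.is_zero():
            raise ValueError("excluded meal intakes must carry a zero vector")


@dataclass
class PersonDayIntake:
    """Per-meal and total nutrient intakes for one participant-day."""

    participant_id: str
    recall_date: str
    meals: list[MealIntake]
    totals: NutrientVector
    meal_frequency_incl_bf: int
    meal_frequency_excl_bf: int
    n_unresolved: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.recall_date)


def meal_nutrients(
    entry: MealEntry, resolved: ResolvedFood | None, grams: float,
    *, portion_audit: str = "",
) -> MealIntake:
    """Nutrients for one meal record.

    ``nutrients = (grams * edible_fraction / 100) * per100g`` of the resolved
    item.  Breast-milk entries are excluded (no nutrient estimate); an
    unresolved code is excluded with reason ``unresolved``.
    """
    if entry.is_breastmilk:
        return MealIntake(
            entry_index=entry.entry_index,
            description=entry.description or "breast milk",
            grams=0.0,
            nutrients=NutrientVector.zero(),
            source="breast_milk",
            excluded=True,
            exclusion_reason=EXCLUDED_BREAST_MILK,
        )
    if grams < 0:
        raise ValueError(f"grams must be >= 0, got {grams}")
    if resolved is None or not resolved.resolved:
        return MealIntake(
            entry_index=entry.entry_index,
            description=entry.description or entry.food_code,
            grams=grams,
            nutrients=NutrientVector.zero(),
            source=SOURCE_UNRESOLVED,
            excluded=True,
            exclusion_reason=EXCLUDED_UNRESOLVED,
        )
    item = resolved.item
    vec = item.per100g.scaled(grams * item.edible_fraction / 100.0)
    return MealIntake(
        entry_index=entry.entry_index,
        description=entry.description or item.name,
        grams=grams,
        nutrients=vec,
        source=resolved.source,
        portion_audit=portion_audit,
    )


def personday_intake(
    recall: PersonDayRecall,
    ctx: FctContext,
    portion_db: PortionDatabase,
    *,
    portion_fallback_g: float | None = None,
    tolerance_minutes: int = 0,
) -> PersonDayIntake:
    """Compute per-meal and total nutrient intakes for one recall day.

    Totals are the componentwise sum over non-excluded meal intakes; meal
    frequencies come from time-based meal grouping; unresolved codes are
    counted.  Portion-lookup failures propagate unless a fallback grams/unit
    is configured.
    """
    meals: list[MealIntake] = []
    n_unresolved = 0
    for entry in sorted(recall.entries, key=lambda e: e.entry_index):
        if entry.is_breastmilk:
            meals.append(meal_nutrients(entry, None, 0.0))
            continue
        resolved = ctx.resolve(
            entry.food_code, entry.description, entry_id=entry.entry_id
        )
        if not resolved.resolved:
            n_unresolved += 1
            logger.info(
                "unresolved food for %s: %s", entry.entry_id, resolved.audit
            )
            meals.append(meal_nutrients(entry, resolved, 0.0))
            continue
        converted = amount_consumed_g(
            entry,
            portion_db,
            food_group=resolved.item.food_group,
            fallback_g=portion_fallback_g,
        )
        audit = (
            f"{converted.level}:{converted.entry.full_key}"
            if converted.entry is not None
            else "fallback"
        )
        meals.append(
            meal_nutrients(entry, resolved, converted.grams, portion_audit=audit)
        )
    totals = vector_sum(m.nutrients for m in meals if not m.excluded)
    return PersonDayIntake(
        participant_id=recall.demographics.participant_id,
        recall_date=recall.demographics.recall_date.isoformat(),
        meals=meals,
        totals=totals,
        meal_frequency_incl_bf=meal_frequency(
            recall, True, tolerance_minutes=tolerance_minutes
        ),
        meal_frequency_excl_bf=meal_frequency(
            recall, False, tolerance_minutes=tolerance_minutes
        ),
        n_unresolved=n_unresolved,
    )


def compute_intakes(
    recalls: Sequence[PersonDayRecall],
    ctx: FctContext,
    portion_db: PortionDatabase,
    **kwargs,
) -> list[tuple[PersonDayRecall, PersonDayIntake]]:
    """Convenience: ``personday_intake`` over a cohort, keeping the pairing."""
    return [(r, personday_intake(r, ctx, portion_db, **kwargs)) for r in recalls]


# ---------------------------------------------------------------------------
# RNI adequacy
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class RNIRow:
    nutrient: str
    age_lo_mo: float
    age_hi_mo: float
    sex: str  # male | female | any
    tier: str
    amount: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"RNI amount must be > 0 for {self.nutrient}")

    def matches(self, nutrient: str, age_months: float, sex: str, tier: str) -> bool:
        return (
            self.nutrient == nutrient
            and self.age_lo_mo <= age_months <= self.age_hi_mo
            and self.sex in ("any", sex)
            and self.tier == tier
        )


class RNITable:
    """Recommended Nutrient Intake reference rows."""

    def __init__(self, rows: Sequence[RNIRow]):
        self.rows = list(rows)

    def lookup(
        self, nutrient: str, age_months: float, sex: str, tier: str = "standard"
    ) -> float | None:
        for row in self.rows:
            if row.matches(nutrient, age_months, sex, tier):
                return row.amount
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RNITable":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            [
                RNIRow(
                    nutrient=str(r["nutrient"]),
                    age_lo_mo=float(r["age_lo_mo"]),
                    age_hi_mo=float(r["age_hi_mo"]),
                    sex=str(r["sex"]),
                    tier=str(r["tier"]),
                    amount=float(r["amount"]),
                )
                for r in doc["rni"]
            ]
        )


def default_rni_table() -> RNITable:
    """The bundled, editable RNI defaults (see ``data/rni_default.yaml``)."""
    with resources.as_file(
        resources.files("dietrecall.data") / "rni_default.yaml"
    ) as p:
        return RNITable.from_yaml(p)


#: default bioavailability tiers applied per nutrient when screening adequacy
DEFAULT_TIERS: dict[str, str] = {
    "iron_mg": "10pct_bioavailability",
    "zinc_mg": "moderate_bioavailability",
}


@dataclass(frozen=True, slots=True)
class SubjectProfile:
    """Age/sex/bioavailability context for RNI matching."""

    age_months: float
    sex: str
    tiers: tuple[tuple[str, str], ...] = ()

    def tier_for(self, nutrient: str) -> str:
        for n, t in self.tiers:
            if n == nutrient:
                return t
        return DEFAULT_TIERS.get(nutrient, "standard")


@dataclass(frozen=True, slots=True)
class Adequacy:
    ratio: float
    meets: bool
    rni_amount: float


def rni_adequacy(
    intake: PersonDayIntake | NutrientVector,
    profile: SubjectProfile,
    rni: RNITable | None = None,
) -> dict[str, Adequacy | None]:
    """Ratio of daily intake to RNI per nutrient; ``meets`` when ratio >= 1.

    Nutrients with no matching RNI row for the profile are ``None``
    (not evaluable).
    """
    if rni is None:
        rni = default_rni_table()
    totals = intake.totals if isinstance(intake, PersonDayIntake) else intake
    result: dict[str, Adequacy | None] = {}
    for nutrient in sorted({row.nutrient for row in rni.rows}):
        amount = rni.lookup(
            nutrient, profile.age_months, profile.sex, profile.tier_for(nutrient)
        )
        if amount is None:
            result[nutrient] = None
            continue
        ratio = getattr(totals, nutrient) / amount
        result[nutrient] = Adequacy(ratio=ratio, meets=ratio >= 1.0, rni_amount=amount)
    return result


# ---------------------------------------------------------------------------
# acceptable energy ranges for young children
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class EnergyRange:
    age_lo_mo: float
    age_hi_mo: float
    breastfed: bool
    lower_kcal: float
    upper_kcal: float

    def __post_init__(self) -> None:
        if not self.lower_kcal < self.upper_kcal:
            raise ValueError("energy range lower bound must be < upper bound")


class EnergyRangeTable:
    def __init__(self, rows: Sequence[EnergyRange]):
        self.rows = list(rows)

    def find(self, age_months: float, breastfed: bool) -> EnergyRange | None:
        for row in self.rows:
            if row.breastfed == breastfed and row.age_lo_mo <= age_months <= row.age_hi_mo:
                return row
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyRangeTable":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            [
                EnergyRange(
                    age_lo_mo=float(r["age_lo_mo"]),
                    age_hi_mo=float(r["age_hi_mo"]),
                    breastfed=bool(r["breastfed"]),
                    lower_kcal=float(r["lower_kcal"]),
                    upper_kcal=float(r["upper_kcal"]),
                )
                for r in doc["energy_ranges"]
            ]
        )


def default_energy_ranges() -> EnergyRangeTable:
    with resources.as_file(
        resources.files("dietrecall.data") / "energy_ranges_default.yaml"
    ) as p:
        return EnergyRangeTable.from_yaml(p)


def energy_range_check(
    energy_kcal: float,
    age_months: float,
    breastfed: bool,
    table: EnergyRangeTable | None = None,
) -> tuple[str, tuple[float, float] | None]:
    """Classify a child-day's energy against the acceptable range.

    Returns ``(classification, (lower, upper))`` with classification one of
    ``below`` / ``within`` / ``above`` (closed interval: endpoints count as
    within), or ``("not_evaluable", None)`` when no range row covers the
    age/breastfed status.
    """
    if table is None:
        table = default_energy_ranges()
    row = table.find(age_months, breastfed)
    if row is None:
        return ("not_evaluable", None)
    bounds = (row.lower_kcal, row.upper_kcal)
    if energy_kcal < row.lower_kcal:
        return ("below", bounds)
    if energy_kcal > row.upper_kcal:
        return ("above", bounds)
    return ("within", bounds)
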