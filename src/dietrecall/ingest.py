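"""Read, join, validate and re-serialize the two-table recall export.

Each 24-h recall is exported as two delimited tables:

* a **demographics** table with exactly one record per participant per recall
  day (who was interviewed, what kind of day it was, declared breastfeeding
  frequency, supplement use), and
* a **meals** table with one record per consumed item — time, location, food
  code or sentinel code, utensil and portion report, breast-milk flag, and
  free-text fields.

``read_recall_tables`` joins them on ``(participant_id, recall_date)`` into
:class:`PersonDayRecall` objects; ``write_normalized`` is its lossless
inverse.  Free text survives round trips via standard CSV quoting, and floats
are written with ``repr`` so re-reading reproduces every field exactly.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import IngestError

logger = logging.getLogger(__name__)

LOCATIONS: tuple[str, ...] = (
    "home",
    "work",
    "friend_house",
    "roadside_vendor",
    "mamalishe",
    "restaurant",
    "hotel",
    "other",
)

DAY_CHARACTERS: tuple[str, ...] = ("typical", "holiday_special", "fasting", "other")

DEMOG_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "recall_date",
    "cohort",
    "age_value",
    "age_unit",
    "sex",
    "day_character",
    "supplement_use",
    "declared_bf_frequency",
)

MEAL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "recall_date",
    "entry_index",
    "time",
    "location",
    "food_code",
    "description",
    "ingredients",
    "utensil",
    "utensil_size",
    "portion_count",
    "is_breastmilk",
    "comments",
)


def parse_clock_time(text: str) -> int:
    """Parse a 24-hour ``HH:MM`` string to minute-of-day (midnight -> 0)."""
    try:
        hh, mm = text.strip().split(":")
        hours, minutes = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise IngestError(f"cannot parse clock time {text!r}") from exc
    if not (0 <= minutes < 60):
        raise IngestError(f"minute component out of range in {text!r}")
    minute = hours * 60 + minutes
    if not (0 <= minute < 1440):
        raise IngestError(f"clock time {text!r} outside [00:00, 24:00)")
    return minute


def format_clock_time(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


def _parse_bool(text: str, context: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "yes", "1"}:
        return True
    if t in {"false", "no", "0", ""}:
        return False
    raise IngestError(f"cannot parse boolean {text!r} for {context}")


@dataclass
class DemographicRecord:
    """One participant-day: who, what kind of day, declared BF frequency."""

    participant_id: str
    recall_date: dt.date
    cohort: str
    age_value: float
    age_unit: str  # "months" for children, "years" for adults
    sex: str
    day_character: str
    supplement_use: bool
    declared_bf_frequency: int

    def __post_init__(self) -> None:
        if self.age_unit not in ("months", "years"):
            raise IngestError(
                f"{self.participant_id}: age_unit must be months|years, "
                f"got {self.age_unit!r}"
            )
        if self.day_character not in DAY_CHARACTERS:
            logger.warning(
                "%s %s: unrecognized day_character %r mapped to 'other'",
                self.participant_id,
                self.recall_date,
                self.day_character,
            )
            self.day_character = "other"
        if self.declared_bf_frequency < 0:
            raise IngestError(
                f"{self.participant_id}: declared_bf_frequency must be >= 0"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.recall_date.isoformat())

    @property
    def age_months(self) -> float:
        return self.age_value if self.age_unit == "months" else self.age_value * 12.0


@dataclass
class MealEntry:
    """One consumed item within a recall day."""

    participant_id: str
    recall_date: dt.date
    entry_index: int
    clock_time: int  # minute-of-day
    location: str
    food_code: str
    description: str
    ingredients: tuple[tuple[str, str], ...] | None  # (text, code) pairs
    utensil: str
    utensil_size: str
    portion_count: float | None
    is_breastmilk: bool
    comments: str = ""

    def __post_init__(self) -> None:
        if self.entry_index < 1:
            raise IngestError(
                f"{self.participant_id}: entry_index must be >= 1, "
                f"got {self.entry_index}"
            )
        if not (0 <= self.clock_time < 1440):
            raise IngestError(
                f"{self.participant_id}: clock_time {self.clock_time} "
                "outside [0, 1440)"
            )
        if self.location not in LOCATIONS:
            logger.warning(
                "%s entry %d: unrecognized location %r mapped to 'other'",
                self.participant_id,
                self.entry_index,
                self.location,
            )
            self.location = "other"
        if not self.is_breastmilk:
            if self.portion_count is None or self.portion_count <= 0:
                raise IngestError(
                    f"{self.participant_id} entry {self.entry_index}: "
                    f"portion_count must be > 0 for food entries, "
                    f"got {self.portion_count!r}"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.recall_date.isoformat())

    @property
    def entry_id(self) -> str:
        return f"{self.participant_id}:{self.recall_date.isoformat()}:{self.entry_index}"


@dataclass
class PersonDayRecall:
    """One demographics record joined to its ordered meal entries."""

    demographics: DemographicRecord
    entries: list[MealEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        key = self.demographics.key
        for e in self.entries:
            if e.key != key:
                raise IngestError(
                    f"entry key {e.key} does not match demographics key {key}"
                )
        indices = [e.entry_index for e in self.entries]
        if len(indices) != len(set(indices)):
            raise IngestError(f"duplicate entry_index values in recall {key}")

    @property
    def key(self) -> tuple[str, str]:
        return self.demographics.key


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _remap_header(row: dict[str, str], column_map: Mapping[str, str] | None) -> dict:
    if not column_map:
        return row
    inverse = {v: k for k, v in column_map.items()}
    return {inverse.get(k, k): v for k, v in row.items()}


def _read_rows(path: Path, column_map: Mapping[str, str] | None) -> list[dict]:
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        return [_remap_header(r, column_map) for r in reader]


def _demog_from_row(row: dict[str, str]) -> DemographicRecord:
    return DemographicRecord(
        participant_id=row["participant_id"].strip(),
        recall_date=dt.date.fromisoformat(row["recall_date"].strip()),
        cohort=row["cohort"].strip(),
        age_value=float(row["age_value"]),
        age_unit=row["age_unit"].strip(),
        sex=row["sex"].strip().lower(),
        day_character=row["day_character"].strip(),
        supplement_use=_parse_bool(row["supplement_use"], "supplement_use"),
        declared_bf_frequency=int(row["declared_bf_frequency"]),
    )


def _entry_from_row(row: dict[str, str]) -> MealEntry:
    ing_raw = (row.get("ingredients") or "").strip()
    ingredients = None
    if ing_raw:
        ingredients = tuple(
            (str(a), str(b)) for a, b in json.loads(ing_raw)
        )
    pc_raw = (row.get("portion_count") or "").strip()
    return MealEntry(
        participant_id=row["participant_id"].strip(),
        recall_date=dt.date.fromisoformat(row["recall_date"].strip()),
        entry_index=int(row["entry_index"]),
        clock_time=parse_clock_time(row["time"]),
        location=row["location"].strip(),
        food_code=(row.get("food_code") or "").strip(),
        description=row.get("description") or "",
        ingredients=ingredients,
        utensil=(row.get("utensil") or "").strip(),
        utensil_size=(row.get("utensil_size") or "").strip(),
        portion_count=float(pc_raw) if pc_raw else None,
        is_breastmilk=_parse_bool(row.get("is_breastmilk", ""), "is_breastmilk"),
        comments=row.get("comments") or "",
    )


def read_recall_tables(
    demog_path: str | Path,
    meals_path: str | Path,
    *,
    demog_column_map: Mapping[str, str] | None = None,
    meals_column_map: Mapping[str, str] | None = None,
) -> list[PersonDayRecall]:
    """Join the two-table export into one :class:`PersonDayRecall` per
    demographics row.

    Meal rows attach by ``(participant_id, recall_date)``.  A meal row with no
    matching demographics row is an error listing the orphan keys; a duplicate
    key in the demographics table is an error.  Participants with zero meal
    rows are returned with empty entries and logged.
    """
    demog_rows = _read_rows(Path(demog_path), demog_column_map)
    meal_rows = _read_rows(Path(meals_path), meals_column_map)

    demogs: dict[tuple[str, str], DemographicRecord] = {}
    for row in demog_rows:
        rec = _demog_from_row(row)
        if rec.key in demogs:
            raise IngestError(
                f"duplicate (participant_id, recall_date) in demographics: {rec.key}"
            )
        demogs[rec.key] = rec

    entries_by_key: dict[tuple[str, str], list[MealEntry]] = {k: [] for k in demogs}
    orphans: set[tuple[str, str]] = set()
    for row in meal_rows:
        entry = _entry_from_row(row)
        if entry.key not in entries_by_key:
            orphans.add(entry.key)
        else:
            entries_by_key[entry.key].append(entry)
    if orphans:
        raise IngestError(
            "meal rows with no matching demographics row: "
            + ", ".join(map(str, sorted(orphans)))
        )

    recalls = []
    for key in sorted(demogs):
        entries = sorted(entries_by_key[key], key=lambda e: e.entry_index)
        if not entries:
            logger.info("participant-day %s has no meal rows", key)
        recalls.append(PersonDayRecall(demographics=demogs[key], entries=entries))
    return recalls


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _fmt_float(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def demog_to_row(d: DemographicRecord) -> list[str]:
    return [
        d.participant_id,
        d.recall_date.isoformat(),
        d.cohort,
        _fmt_float(d.age_value),
        d.age_unit,
        d.sex,
        d.day_character,
        "true" if d.supplement_use else "false",
        str(d.declared_bf_frequency),
    ]


def entry_to_row(e: MealEntry) -> list[str]:
    return [
        e.participant_id,
        e.recall_date.isoformat(),
        str(e.entry_index),
        format_clock_time(e.clock_time),
        e.location,
        e.food_code,
        e.description,
        json.dumps([list(p) for p in e.ingredients]) if e.ingredients else "",
        e.utensil,
        e.utensil_size,
        _fmt_float(e.portion_count),
        "true" if e.is_breastmilk else "false",
        e.comments,
    ]


def write_normalized(
    recalls: Sequence[PersonDayRecall],
    out_demog_path: str | Path,
    out_meals_path: str | Path,
) -> tuple[Path, Path]:
    """Serialize recalls back to the two-table dialect (lossless round trip)."""
    out_demog_path = Path(out_demog_path)
    out_meals_path = Path(out_meals_path)
    ordered = sorted(recalls, key=lambda r: r.key)
    with open(out_demog_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DEMOG_COLUMNS)
        for r in ordered:
            writer.writerow(demog_to_row(r.demographics))
    with open(out_meals_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEAL_COLUMNS)
        for r in ordered:
            for e in sorted(r.entries, key=lambda e: e.entry_index):
                writer.writerow(entry_to_row(e))
    return out_demog_path, out_meals_path


def total_entry_count(recalls: Iterable[PersonDayRecall]) -> int:
    return sum(len(r.entries) for r in recalls)
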