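"""Convert utensil-based portion reports to grams consumed.

Interviewers record portions against a small set of reference serving
utensils (bowl, cup, tumbler, plate, tablespoon, teaspoon, saucer) with a
size class.  A portion-size database maps ``(food code or food group,
utensil, size)`` to grams per unit; densities are baked into the gram
estimates rather than modeled.  Lookup precedence is food-specific before
food-group default, and the matched entry is returned for audit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

from .errors import PortionError, PortionLookupError

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import MealEntry

logger = logging.getLogger(__name__)

#: the seven reference serving-size utensils shipped with the default registry
REFERENCE_UTENSILS: tuple[str, ...] = (
    "bowl",
    "cup",
    "tumbler",
    "plate",
    "tablespoon",
    "teaspoon",
    "saucer",
)

SIZE_CLASSES: tuple[str, ...] = ("small", "medium", "large")

PORTION_COLUMNS = ("food_code_or_group", "utensil", "size", "grams_per_unit", "provenance")


@dataclass(frozen=True)
class UtensilRegistry:
    """Named utensils with their size classes; names must be unique."""

    utensils: tuple[str, ...] = REFERENCE_UTENSILS
    sizes: tuple[str, ...] = SIZE_CLASSES

    def __post_init__(self) -> None:
        if len(set(self.utensils)) != len(self.utensils):
            raise PortionError("utensil names must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.utensils


@dataclass(frozen=True, slots=True)
class PortionEntry:
    """Gram weight of one unit of a (food-or-group, utensil, size) serving."""

    key: str  # food code or food group
    utensil: str
    size: str
    grams_per_unit: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.grams_per_unit <= 0:
            raise PortionError(
                f"grams_per_unit must be > 0 for {(self.key, self.utensil, self.size)}"
            )

    @property
    def full_key(self) -> tuple[str, str, str]:
        return (self.key, self.utensil, self.size)


@dataclass(frozen=True, slots=True)
class ConvertedAmount:
    """Gram conversion result, carrying the matched entry for audit."""

    grams: float
    entry: PortionEntry | None
    level: str  # "food" | "group" | "fallback"

    def __float__(self) -> float:
        return self.grams


class PortionDatabase:
    """Portion entries with food-specific-before-group-default precedence."""

    def __init__(self, entries=()):
        self._entries: dict[tuple[str, str, str], PortionEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: PortionEntry) -> None:
        if entry.full_key in self._entries:
            raise PortionError(f"duplicate portion key {entry.full_key}")
        self._entries[entry.full_key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, key: str, utensil: str, size: str) -> PortionEntry | None:
        return self._entries.get((key, utensil, size))

    def lookup(
        self,
        food_code: str,
        utensil: str,
        size: str,
        food_group: str | None = None,
    ) -> tuple[PortionEntry, str]:
        """Return ``(entry, level)`` where level is ``"food"`` or ``"group"``.

        Raises :class:`PortionLookupError` when neither level matches.
        """
        entry = self._entries.get((food_code, utensil, size))
        if entry is not None:
            return entry, "food"
        if food_group is not None:
            entry = self._entries.get((food_group, utensil, size))
            if entry is not None:
                return entry, "group"
        raise PortionLookupError(food_code, food_group, utensil, size)


def load_portion_db(path: str | Path, *, delimiter: str | None = None) -> PortionDatabase:
    """Load a portion-size database from delimited text
    (``food_code_or_group, utensil, size, grams_per_unit, provenance``).

    Nonpositive gram weights and duplicate keys are errors.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            delimiter = "\t" if "\t" in fh.readline() else ","
    db = PortionDatabase()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for row in reader:
            db.add(
                PortionEntry(
                    key=row["food_code_or_group"].strip(),
                    utensil=row["utensil"].strip(),
                    size=row["size"].strip(),
                    grams_per_unit=float(row["grams_per_unit"]),
                    provenance=(row.get("provenance") or "").strip(),
                )
            )
    return db


def write_portion_db(db: PortionDatabase, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PORTION_COLUMNS)
        for entry in sorted(db, key=lambda e: e.full_key):
            writer.writerow(
                [entry.key, entry.utensil, entry.size,
                 repr(entry.grams_per_unit), entry.provenance]
            )
    return path


def amount_consumed_g(
    entry: "MealEntry",
    db: PortionDatabase,
    *,
    food_group: str | None = None,
    fallback_g: float | None = None,
) -> ConvertedAmount:
    """Grams consumed for a food meal entry.

    ``grams = portion_count * grams_per_unit`` of the highest-precedence
    matching portion entry (food-specific, then the food-group default when
    ``food_group`` is given).  A missing mapping raises
    :class:`PortionLookupError` unless ``fallback_g`` (grams per unit) is
    configured, in which case the fallback is used with a logged warning.

    Breast-milk entries carry no portion report; passing one is a contract
    violation.
    """
    if entry.is_breastmilk:
        raise ValueError("amount_consumed_g called on a breast-milk entry")
    if entry.portion_count is None or entry.portion_count <= 0:
        raise ValueError(f"portion_count must be > 0, got {entry.portion_count!r}")
    try:
        match, level = db.lookup(
            entry.food_code, entry.utensil, entry.utensil_size, food_group
        )
    except PortionLookupError:
        if fallback_g is None:
            raise
        logger.warning(
            "no portion entry for %r (%s/%s); using fallback %.1f g/unit",
            entry.food_code,
            entry.utensil,
            entry.utensil_size,
            fallback_g,
        )
        return ConvertedAmount(entry.portion_count * fallback_g, None, "fallback")
    if level == "group":
        logger.debug(
            "portion for %r fell back to group default %r",
            entry.food_code,
            match.key,
        )
    return ConvertedAmount(entry.portion_count * match.grams_per_unit, match, level)
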