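"""Food-composition tables, the sentinel-code resolution cascade, and recipes.

A food-composition table (FCT) maps food codes to nutrient content per 100 g
edible portion.  Field recalls reference foods by the same codes, with two
reserved sentinel codes: ``9999`` marks an unknown meal to be resolved after
collection (against a secondary FCT or a newly created recipe) and ``8888``
marks a meal captured as a new recipe.  Resolution of sentinel codes is driven
by an explicit, reviewable assignment table — there is no fuzzy text matching,
mirroring a manual nutritionist review workflow.

Nutrients for new recipes are computed per 100 g of the dish: ingredient
amounts (raw grams, scaled by each ingredient's edible fraction) contribute
proportionally, and the denominator is the cooked weight when recorded,
otherwise the raw ingredient total.  Nutrient retention factors are not
applied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import FCTError
from .nutrivec import NUTRIENTS, NutrientVector

logger = logging.getLogger(__name__)

#: sentinel food code for an unknown meal awaiting manual code assignment
UNKNOWN_CODE = "9999"
#: sentinel food code for a meal captured as a new recipe
NEW_RECIPE_CODE = "8888"

SENTINEL_CODES = frozenset({UNKNOWN_CODE, NEW_RECIPE_CODE})

_BASE_COLUMNS = ("code", "name", "food_group", "edible_fraction")


@dataclass(frozen=True, slots=True)
class FoodItem:
    """One food with nutrient content per 100 g edible portion."""

    code: str
    name: str
    food_group: str
    per100g: NutrientVector
    edible_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.code:
            raise FCTError("food code must be nonempty")
        if self.code in SENTINEL_CODES:
            raise FCTError(f"sentinel value {self.code!r} used as a food code")
        if not (0.0 < self.edible_fraction <= 1.0):
            raise FCTError(
                f"edible_fraction must be in (0, 1], got {self.edible_fraction!r} "
                f"for code {self.code!r}"
            )


@dataclass
class FCTable:
    """A food-composition table: unique codes -> :class:`FoodItem`."""

    source_label: str
    items: dict[str, FoodItem] = field(default_factory=dict)
    fiber_unit: str = "mg"

    def add(self, item: FoodItem) -> None:
        if item.code in self.items:
            raise FCTError(
                f"duplicate code {item.code!r} in table {self.source_label!r}"
            )
        self.items[item.code] = item

    def get(self, code: str) -> FoodItem | None:
        return self.items.get(code)

    def __contains__(self, code: str) -> bool:
        return code in self.items

    def __len__(self) -> int:
        return len(self.items)


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_fct(
    path: str | Path,
    source_label: str,
    *,
    delimiter: str | None = None,
    fiber_unit: str = "mg",
) -> FCTable:
    """Load a food-composition table from delimited text.

    The header must name ``code, name, food_group, edible_fraction`` plus any
    of the canonical nutrient columns (:data:`dietrecall.nutrivec.NUTRIENTS`).
    Nutrient columns absent from the file default to 0 with a logged warning.

    Raises :class:`FCTError` on duplicate codes (naming both rows), negative
    nutrient values, or a sentinel value used as a code.
    """
    path = Path(path)
    delim = delimiter or _detect_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise FCTError(f"{path}: empty file, expected a header row")
        cols = list(reader.fieldnames)
        missing_base = [c for c in _BASE_COLUMNS if c not in cols]
        if missing_base:
            raise FCTError(f"{path}: missing required columns {missing_base}")
        missing_nutrients = [n for n in NUTRIENTS if n not in cols]
        if missing_nutrients:
            logger.warning(
                "%s: nutrient columns %s absent, defaulting to 0",
                path,
                missing_nutrients,
            )
        table = FCTable(source_label=source_label, fiber_unit=fiber_unit)
        seen_rows: dict[str, int] = {}
        for rownum, row in enumerate(reader, start=2):
            code = (row["code"] or "").strip()
            if code in seen_rows:
                raise FCTError(
                    f"{path}: duplicate code {code!r} in rows "
                    f"{seen_rows[code]} and {rownum}"
                )
            amounts = {}
            for n in NUTRIENTS:
                raw = (row.get(n) or "").strip()
                v = float(raw) if raw else 0.0
                if v < 0:
                    raise FCTError(
                        f"{path}: negative {n} ({v}) for code {code!r} in row {rownum}"
                    )
                amounts[n] = v
            item = FoodItem(
                code=code,
                name=(row["name"] or "").strip(),
                food_group=(row["food_group"] or "").strip(),
                per100g=NutrientVector(**amounts),
                edible_fraction=float(row["edible_fraction"]),
            )
            table.add(item)
            seen_rows[code] = rownum
    return table


def write_fct(table: FCTable, path: str | Path, *, delimiter: str = ",") -> Path:
    """Write a table back to delimited text; floats use ``repr`` so that a
    write/reload round trip reproduces all items exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(_BASE_COLUMNS) + list(NUTRIENTS))
        for code in sorted(table.items):
            it = table.items[code]
            writer.writerow(
                [it.code, it.name, it.food_group, repr(it.edible_fraction)]
                + [repr(getattr(it.per100g, n)) for n in NUTRIENTS]
            )
    return path


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Ingredient:
    code: str
    grams: float

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise FCTError(f"ingredient {self.code!r} mass must be > 0")


@dataclass(frozen=True, slots=True)
class Recipe:
    """A field-captured recipe in the new-recipe (8888) namespace."""

    recipe_id: str
    description: str
    ingredients: tuple[Ingredient, ...]
    cooked_weight_g: float | None = None
    method_notes: str = ""
    source_doc: str = ""

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise FCTError(f"recipe {self.recipe_id!r} has no ingredients")
        if self.cooked_weight_g is not None and self.cooked_weight_g <= 0:
            raise FCTError(
                f"recipe {self.recipe_id!r}: cooked_weight_g must be > 0"
            )

    @classmethod
    def build(
        cls,
        recipe_id: str,
        description: str,
        ingredients: Iterable[tuple[str, float]],
        cooked_weight_g: float | None = None,
        method_notes: str = "",
        source_doc: str = "",
    ) -> "Recipe":
        return cls(
            recipe_id=recipe_id,
            description=description,
            ingredients=tuple(Ingredient(c, float(g)) for c, g in ingredients),
            cooked_weight_g=cooked_weight_g,
            method_notes=method_notes,
            source_doc=source_doc,
        )


class RecipeRegistry:
    """Registry of recipes keyed by recipe id, persisted as YAML."""

    def __init__(self, recipes: Iterable[Recipe] = ()):
        self._recipes: dict[str, Recipe] = {}
        for r in recipes:
            self.register(r)

    def register(self, recipe: Recipe) -> "RecipeRegistry":
        if recipe.recipe_id in self._recipes:
            raise FCTError(f"recipe id {recipe.recipe_id!r} already registered")
        self._recipes[recipe.recipe_id] = recipe
        return self

    def get(self, recipe_id: str) -> Recipe | None:
        return self._recipes.get(recipe_id)

    def __contains__(self, recipe_id: str) -> bool:
        return recipe_id in self._recipes

    def __len__(self) -> int:
        return len(self._recipes)

    def __iter__(self):
        return iter(self._recipes.values())

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "recipes": [
                {
                    "recipe_id": r.recipe_id,
                    "description": r.description,
                    "ingredients": [
                        {"code": i.code, "grams": i.grams} for i in r.ingredients
                    ],
                    "cooked_weight_g": r.cooked_weight_g,
                    "method_notes": r.method_notes,
                    "source_doc": r.source_doc,
                }
                for r in sorted(self._recipes.values(), key=lambda r: r.recipe_id)
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RecipeRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        reg = cls()
        for rec in doc.get("recipes", []):
            reg.register(
                Recipe.build(
                    recipe_id=str(rec["recipe_id"]),
                    description=rec.get("description", ""),
                    ingredients=[
                        (str(i["code"]), float(i["grams"]))
                        for i in rec["ingredients"]
                    ],
                    cooked_weight_g=rec.get("cooked_weight_g"),
                    method_notes=rec.get("method_notes", ""),
                    source_doc=rec.get("source_doc", ""),
                )
            )
        return reg


def register_recipe(recipe: Recipe, registry: RecipeRegistry) -> RecipeRegistry:
    """Add ``recipe`` to ``registry``; duplicate ids are an error."""
    return registry.register(recipe)


def load_assignments(path: str | Path) -> dict[str, str]:
    """Load the code-assignment override map (description or entry id -> code
    or recipe id) from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return {str(k): str(v) for k, v in (doc.get("assignments") or {}).items()}


def save_assignments(assignments: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"assignments": dict(sorted(assignments.items()))},
            fh,
            sort_keys=False,
            allow_unicode=True,
        )
    return path


# ---------------------------------------------------------------------------
# recipe nutrient arithmetic
# ---------------------------------------------------------------------------


def _tables_of(lookup) -> list[FCTable]:
    if isinstance(lookup, FCTable):
        return [lookup]
    if isinstance(lookup, FctContext):
        return lookup.tables
    return [t for t in lookup if t is not None]


def recipe_nutrients_per_100g(recipe: Recipe, lookup) -> NutrientVector:
    """Per-100 g nutrient vector of a recipe.

    Each ingredient contributes ``grams * edible_fraction * per100g / 100``;
    the total is renormalised to 100 g of dish using the cooked weight when
    present, otherwise the raw ingredient mass total (a logged warning notes
    that moisture change is then ignored).  Retention factors are not applied.

    ``lookup`` may be an :class:`FCTable`, a sequence of tables searched in
    order, or an :class:`FctContext`.
    """
    tables = _tables_of(lookup)
    total = NutrientVector.zero()
    raw_mass = 0.0
    for ing in recipe.ingredients:
        item = None
        for t in tables:
            item = t.get(ing.code)
            if item is not None:
                break
        if item is None:
            raise FCTError(
                f"recipe {recipe.recipe_id!r}: ingredient {ing.code!r} "
                "not found in any food-composition table"
            )
        total = total + item.per100g.scaled(ing.grams * item.edible_fraction / 100.0)
        raw_mass += ing.grams
    if recipe.cooked_weight_g is not None:
        denom = recipe.cooked_weight_g
    else:
        denom = raw_mass
        logger.warning(
            "recipe %s: no cooked weight recorded, using raw ingredient total "
            "%.1f g as yield (moisture change ignored)",
            recipe.recipe_id,
            raw_mass,
        )
    if denom <= 0:
        raise FCTError(f"recipe {recipe.recipe_id!r}: yield mass must be > 0")
    return total.scaled(100.0 / denom)


# ---------------------------------------------------------------------------
# resolution cascade
# ---------------------------------------------------------------------------

SOURCE_PRIMARY = "primary_fct"
SOURCE_SECONDARY = "secondary_fct"
SOURCE_RECIPE = "recipe"
SOURCE_UNRESOLVED = "unresolved"


@dataclass(frozen=True, slots=True)
class ResolvedFood:
    """Outcome of the code-resolution cascade."""

    source: str
    item: FoodItem | None
    audit: str

    def __post_init__(self) -> None:
        if (self.item is None) != (self.source == SOURCE_UNRESOLVED):
            raise FCTError("item must be present iff source != unresolved")

    @property
    def resolved(self) -> bool:
        return self.source != SOURCE_UNRESOLVED


def _recipe_item(recipe: Recipe, tables: Sequence[FCTable]) -> FoodItem:
    vec = recipe_nutrients_per_100g(recipe, tables)
    return FoodItem(
        code=f"R:{recipe.recipe_id}",
        name=recipe.description or recipe.recipe_id,
        food_group="recipe",
        per100g=vec,
        edible_fraction=1.0,
    )


def resolve_code(
    code: str,
    description: str,
    primary: FCTable,
    secondary: FCTable | None = None,
    assignments: Mapping[str, str] | None = None,
    recipes: RecipeRegistry | None = None,
    *,
    entry_id: str | None = None,
    supplemental: FCTable | None = None,
) -> ResolvedFood:
    """Resolve a recorded food code to a food item.

    Deterministic cascade:

    1. ``code`` found in the primary table -> that item.
    2. ``code == UNKNOWN_CODE`` (9999) with an assignment (keyed by entry id
       or description) to a primary/secondary code -> that table's item.
    3. ``code == NEW_RECIPE_CODE`` (8888), or the assignment names a
       registered recipe -> recipe-derived pseudo-item (nutrients per 100 g).
    4. otherwise unresolved, with the resolution path in ``audit``.

    An 8888 code with no recipe assigned yields ``unresolved`` with a
    distinct audit message rather than a hard error.
    """
    assignments = assignments or {}
    recipes = recipes or RecipeRegistry()
    # supplemental tables (e.g. tertiary-source ingredients) participate in
    # recipe ingredient lookup only, never in direct code hits
    tables = [t for t in (primary, secondary, supplemental) if t is not None]
    trail: list[str] = []

    if code not in SENTINEL_CODES:
        item = primary.get(code)
        if item is not None:
            return ResolvedFood(
                SOURCE_PRIMARY, item, f"code {code!r} found in primary table"
            )
        trail.append(f"code {code!r} not in primary table")

    assigned: str | None = None
    assigned_via = ""
    if entry_id is not None and entry_id in assignments:
        assigned = assignments[entry_id]
        assigned_via = f"entry id {entry_id!r}"
    elif description in assignments:
        assigned = assignments[description]
        assigned_via = f"description {description!r}"

    if assigned is not None:
        trail.append(f"assignment via {assigned_via} -> {assigned!r}")
        item = primary.get(assigned)
        if item is not None:
            return ResolvedFood(SOURCE_PRIMARY, item, "; ".join(trail))
        if secondary is not None:
            item = secondary.get(assigned)
            if item is not None:
                return ResolvedFood(SOURCE_SECONDARY, item, "; ".join(trail))
        recipe = recipes.get(assigned)
        if recipe is not None:
            trail.append(f"recipe {recipe.recipe_id!r} nutrients computed per 100 g")
            return ResolvedFood(
                SOURCE_RECIPE, _recipe_item(recipe, tables), "; ".join(trail)
            )
        trail.append(f"assigned value {assigned!r} matches no table or recipe")
        return ResolvedFood(SOURCE_UNRESOLVED, None, "; ".join(trail))

    if code == NEW_RECIPE_CODE:
        trail.append(f"new-recipe code {NEW_RECIPE_CODE} with no recipe assigned")
        return ResolvedFood(SOURCE_UNRESOLVED, None, "; ".join(trail))
    if code == UNKNOWN_CODE:
        trail.append(f"unknown-meal code {UNKNOWN_CODE} with no assignment")
        return ResolvedFood(SOURCE_UNRESOLVED, None, "; ".join(trail))
    trail.append("no assignment; unresolved")
    return ResolvedFood(SOURCE_UNRESOLVED, None, "; ".join(trail))


@dataclass
class FctContext:
    """Everything needed to resolve a recorded food code."""

    primary: FCTable
    secondary: FCTable | None = None
    supplemental: FCTable | None = None
    assignments: dict[str, str] = field(default_factory=dict)
    recipes: RecipeRegistry = field(default_factory=RecipeRegistry)

    @property
    def tables(self) -> list[FCTable]:
        return [
            t for t in (self.primary, self.secondary, self.supplemental) if t is not None
        ]

    def find_item(self, code: str) -> FoodItem | None:
        for t in self.tables:
            item = t.get(code)
            if item is not None:
                return item
        return None

    def resolve(
        self, code: str, description: str, *, entry_id: str | None = None
    ) -> ResolvedFood:
        return resolve_code(
            code,
            description,
            self.primary,
            self.secondary,
            self.assignments,
            self.recipes,
            entry_id=entry_id,
            supplemental=self.supplemental,
        )
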