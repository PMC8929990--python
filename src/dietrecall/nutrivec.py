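"""Nutrient amount vectors.

A :class:`NutrientVector` holds amounts of the eleven nutrients the pipeline
reports, either per 100 g edible portion (food-composition entries, recipe
results) or per meal / per person-day (intake results).  The components are:

==================  =========================================
field               unit
==================  =========================================
energy_kcal         kcal
protein_g           g
animal_protein_g    g (subset of protein_g)
fat_g               g
carb_g              g
fiber               amount in the configured fiber unit
calcium_mg          mg
iron_mg             mg
zinc_mg             mg
vitA_ug_RE          μg retinol equivalents
folate_ug           μg
==================  =========================================

The fiber unit is metadata carried by the food-composition table (default
``"mg"``); it is never converted silently.  Vectors form a cone: addition and
scaling by a nonnegative scalar are componentwise and preserve the invariants
(every component >= 0, animal-source protein <= total protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterator, Mapping

NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "animal_protein_g",
    "fat_g",
    "carb_g",
    "fiber",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
    "vitA_ug_RE",
    "folate_ug",
)

# relative slack for the animal<=total protein invariant so that sums of many
# float terms do not spuriously fail validation
_REL_EPS = 1e-9


@dataclass(frozen=True, slots=True)
class NutrientVector:
    energy_kcal: float = 0.0
    protein_g: float = 0.0
    animal_protein_g: float = 0.0
    fat_g: float = 0.0
    carb_g: float = 0.0
    fiber: float = 0.0
    calcium_mg: float = 0.0
    iron_mg: float = 0.0
    zinc_mg: float = 0.0
    vitA_ug_RE: float = 0.0
    folate_ug: float = 0.0

    def __post_init__(self) -> None:
        for name in NUTRIENTS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"nutrient {name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"nutrient {name} must be >= 0, got {v!r}")
        slack = _REL_EPS * max(1.0, self.protein_g)
        if self.animal_protein_g > self.protein_g + slack:
            raise ValueError(
                f"animal_protein_g ({self.animal_protein_g}) exceeds "
                f"protein_g ({self.protein_g})"
            )

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return NutrientVector(
            **{n: getattr(self, n) + getattr(other, n) for n in NUTRIENTS}
        )

    def scaled(self, k: float) -> "NutrientVector":
        """Componentwise scaling by ``k`` (must be >= 0)."""
        if k < 0:
            raise ValueError(f"scale factor must be >= 0, got {k}")
        return NutrientVector(**{n: getattr(self, n) * k for n in NUTRIENTS})

    def __mul__(self, k: float) -> "NutrientVector":
        return self.scaled(k)

    __rmul__ = __mul__

    # -- conversions and comparisons ---------------------------------------

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in NUTRIENTS}

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, n) for n in NUTRIENTS)

    @classmethod
    def zero(cls) -> "NutrientVector":
        return cls()

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "NutrientVector":
        unknown = set(m) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown nutrient fields: {sorted(unknown)}")
        return cls(**{n: float(m.get(n, 0.0)) for n in NUTRIENTS})

    def allclose(
        self, other: "NutrientVector", rel: float = 1e-9, abs_tol: float = 1e-12
    ) -> bool:
        return all(
            math.isclose(a, b, rel_tol=rel, abs_tol=abs_tol)
            for a, b in zip(self, other)
        )

    def is_zero(self) -> bool:
        return all(v == 0.0 for v in self)


def vector_sum(vectors) -> NutrientVector:
    """Componentwise sum of an iterable of vectors (empty -> zero vector)."""
    total = NutrientVector.zero()
    for v in vectors:
        total = total + v
    return total


# keep dataclass fields and the canonical nutrient order in sync
assert tuple(f.name for f in fields(NutrientVector)) == NUTRIENTS
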