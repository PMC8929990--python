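"""Meal grouping and chrono-nutrition analytics.

A *meal* is any set of foods, snacks and beverages consumed at the same time:
entries whose recorded clock times fall within the grouping tolerance
(default 0 minutes, i.e. the exact same recorded time) merge into one
:class:`MealGroup` by single linkage on sorted times.  Groups are ranked by
time into meal-order positions (1 = earliest), which drive meal frequency,
energy-by-meal-order summaries, food-away-from-home (FAFH) energy shares,
food-frequency rankings and meal-timing histograms.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import MealEntry, PersonDayRecall

if TYPE_CHECKING:  # pragma: no cover
    from .nutrients import PersonDayIntake

#: locale-independent weekday names indexed by ``date.weekday()``
WEEKDAYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass
class MealGroup:
    """Entries consumed at (tolerance-)identical times, ranked within the day."""

    time: int  # minute-of-day of the earliest member
    order: int  # 1 = earliest group of the day
    entries: list[MealEntry] = field(default_factory=list)

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(sorted({e.location for e in self.entries}))

    @property
    def is_breastmilk_only(self) -> bool:
        return all(e.is_breastmilk for e in self.entries)


def group_meals(recall: PersonDayRecall, tolerance_minutes: int = 0) -> list[MealGroup]:
    """Partition a recall's entries into meal groups.

    Entries whose times differ by at most ``tolerance_minutes`` merge
    (single-linkage on sorted times).  Groups are ordered by time; ties in
    time break by ``entry_index``.
    """
    entries = sorted(recall.entries, key=lambda e: (e.clock_time, e.entry_index))
    groups: list[MealGroup] = []
    for e in entries:
        if groups and e.clock_time - groups[-1].entries[-1].clock_time <= tolerance_minutes:
            groups[-1].entries.append(e)
        else:
            groups.append(MealGroup(time=e.clock_time, order=len(groups) + 1, entries=[e]))
    return groups


def meal_frequency(
    recall: PersonDayRecall,
    include_breastmilk: bool = True,
    *,
    tolerance_minutes: int = 0,
) -> int:
    """Number of meal groups; breast-milk-only groups are excluded when
    ``include_breastmilk`` is false."""
    groups = group_meals(recall, tolerance_minutes)
    if include_breastmilk:
        return len(groups)
    return sum(1 for g in groups if not g.is_breastmilk_only)


# ---------------------------------------------------------------------------
# energy by meal order
# ---------------------------------------------------------------------------


def meal_group_energies(
    recall: PersonDayRecall,
    intake: "PersonDayIntake",
    *,
    tolerance_minutes: int = 0,
) -> list[tuple[MealGroup, float]]:
    """Per-group energy (kcal), summed over non-excluded member entries."""
    energy_by_index = {
        m.entry_index: m.nutrients.energy_kcal for m in intake.meals
    }
    out = []
    for g in group_meals(recall, tolerance_minutes):
        out.append((g, sum(energy_by_index.get(e.entry_index, 0.0) for e in g.entries)))
    return out


def _stratum_label(recall: PersonDayRecall, by: Sequence[str]) -> tuple:
    label = []
    for b in by:
        if b == "sex":
            label.append(recall.demographics.sex)
        elif b == "weekday":
            label.append(WEEKDAYS[recall.demographics.recall_date.weekday()])
        elif b == "cohort":
            label.append(recall.demographics.cohort)
        else:
            raise ValueError(f"unknown stratifier {b!r}")
    return tuple(label)


def energy_by_meal_order(
    persondays: Sequence[tuple[PersonDayRecall, "PersonDayIntake"]],
    by: Sequence[str] = ("sex",),
    *,
    tolerance_minutes: int = 0,
) -> pd.DataFrame:
    """Mean energy and share of daily energy per meal-order position per
    stratum.

    The share at each order position is the stratum's total energy consumed
    at that position divided by the stratum's total daily energy, so shares
    within a stratum sum to 1 and ``mean_kcal * n`` summed over positions
    recovers the stratum's total energy.  Empty strata yield no rows.
    """
    rows = []
    for recall, intake in persondays:
        label = _stratum_label(recall, by)
        for g, energy in meal_group_energies(
            recall, intake, tolerance_minutes=tolerance_minutes
        ):
            rows.append((*label, g.order, energy))
    if not rows:
        return pd.DataFrame(columns=[*by, "meal_order", "n", "mean_kcal", "share"])
    df = pd.DataFrame(rows, columns=[*by, "meal_order", "energy"])
    grouped = (
        df.groupby([*by, "meal_order"], sort=True)["energy"]
        .agg(n="count", mean_kcal="mean", total="sum")
        .reset_index()
    )
    stratum_totals = df.groupby(list(by))["energy"].sum()
    keys = grouped[list(by)].apply(tuple, axis=1)
    if len(by) == 1:
        keys = grouped[by[0]]
    denom = keys.map(stratum_totals).astype(float)
    grouped["share"] = np.where(denom > 0, grouped["total"] / denom, np.nan)
    return grouped.drop(columns="total")


# ---------------------------------------------------------------------------
# food away from home
# ---------------------------------------------------------------------------


def fafh_energy_share(
    recall: PersonDayRecall, intake: "PersonDayIntake"
) -> float | None:
    """Share of daily energy consumed away from home, in [0, 1].

    ``None`` (not evaluable) when total daily energy is zero.
    """
    energy_by_index = {m.entry_index: m.nutrients.energy_kcal for m in intake.meals}
    total = sum(energy_by_index.values())
    if total <= 0:
        return None
    away = sum(
        energy_by_index.get(e.entry_index, 0.0)
        for e in recall.entries
        if e.location != "home"
    )
    return away / total


def has_away_meal(recall: PersonDayRecall) -> bool:
    return any(e.location != "home" and not e.is_breastmilk for e in recall.entries)


def fafh_summary(
    persondays: Sequence[tuple[PersonDayRecall, "PersonDayIntake"]],
    by: Sequence[str] = ("sex",),
) -> dict:
    """Population FAFH summary.

    Median away-from-home energy share is reported among persons with at
    least one away-from-home food record (matching the convention of
    conditioning on eating out at all), per stratum and overall.
    """
    shares: dict[tuple, list[float]] = {}
    overall: list[float] = []
    for recall, intake in persondays:
        if not has_away_meal(recall):
            continue
        s = fafh_energy_share(recall, intake)
        if s is None:
            continue
        overall.append(s)
        shares.setdefault(_stratum_label(recall, by), []).append(s)
    return {
        "median_share_overall": statistics.median(overall) if overall else None,
        "median_share_by": {
            k: statistics.median(v) for k, v in sorted(shares.items())
        },
        "n_by": {k: len(v) for k, v in sorted(shares.items())},
    }


def location_share_table(recalls: Iterable[PersonDayRecall]) -> pd.DataFrame:
    """Percent of food meal records by consumption location."""
    from .ingest import LOCATIONS

    counts = {loc: 0 for loc in LOCATIONS}
    total = 0
    for r in recalls:
        for e in r.entries:
            if e.is_breastmilk:
                continue
            counts[e.location] += 1
            total += 1
    return pd.DataFrame(
        {
            "location": list(counts),
            "n": list(counts.values()),
            "pct": [100.0 * c / total if total else np.nan for c in counts.values()],
        }
    )


# ---------------------------------------------------------------------------
# food frequency and timing
# ---------------------------------------------------------------------------


def food_frequency_table(
    recalls: Iterable[PersonDayRecall],
    *,
    top_n: int | None = None,
    stratifier: Callable[[PersonDayRecall], str] | None = None,
    name_of: Callable[[MealEntry], str] | None = None,
):
    """Ranked counts of meal records per food.

    Counts are of meal records across all recalls (breast-milk records
    excluded), ranked descending with ties broken alphabetically.  With a
    ``stratifier`` the result is a dict of per-stratum ranked lists.
    """
    if name_of is None:
        name_of = lambda e: e.description or e.food_code  # noqa: E731

    def _rank(counts: dict[str, int]) -> list[tuple[str, int]]:
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:top_n] if top_n is not None else ranked

    if stratifier is None:
        counts: dict[str, int] = {}
        for r in recalls:
            for e in r.entries:
                if not e.is_breastmilk:
                    name = name_of(e)
                    counts[name] = counts.get(name, 0) + 1
        return _rank(counts)

    per_stratum: dict[str, dict[str, int]] = {}
    for r in recalls:
        bucket = per_stratum.setdefault(stratifier(r), {})
        for e in r.entries:
            if not e.is_breastmilk:
                name = name_of(e)
                bucket[name] = bucket.get(name, 0) + 1
    return {k: _rank(v) for k, v in sorted(per_stratum.items())}


def timing_histogram(
    recalls: Iterable[PersonDayRecall],
    bin_minutes: int = 60,
    *,
    tolerance_minutes: int = 0,
    include_breastmilk: bool = False,
) -> np.ndarray:
    """Counts of meal groups per clock-time bin (half-open ``[t, t+bin)``).

    ``bin_minutes`` must divide 1440.  The totals over bins equal the number
    of meal groups counted.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError(f"bin_minutes ({bin_minutes}) must divide 1440")
    counts = np.zeros(1440 // bin_minutes, dtype=int)
    for r in recalls:
        for g in group_meals(r, tolerance_minutes):
            if not include_breastmilk and g.is_breastmilk_only:
                continue
            counts[g.time // bin_minutes] += 1
    return counts


def histogram_peak_minute(
    counts: np.ndarray, bin_minutes: int, *, window: tuple[int, int] | None = None
) -> int:
    """Bin-center minute of the largest histogram bin, optionally restricted
    to a ``[lo, hi)`` minute window (used for mode recovery)."""
    centers = np.arange(len(counts)) * bin_minutes + bin_minutes / 2
    mask = np.ones(len(counts), dtype=bool)
    if window is not None:
        mask = (centers >= window[0]) & (centers < window[1])
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(counts[idx])]
    return int(centers[best])
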