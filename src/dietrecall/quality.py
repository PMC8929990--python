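"""Interview-review and real-time quality-control rules, plus field reports.

Rules mirror the checks a field supervisor runs while collection is ongoing:

``BF_MISMATCH``
    (error) the declared breastfeeding frequency must equal the number of
    breast-milk meal entries recorded with timing and location.
``TWO_MORNINGS``
    (warning) heuristic for a recall that spans two mornings (e.g. 08:00
    yesterday to 08:00 today): entry times in recorded order decrease at some
    point, and both the pre- and post-decrease segments contain a time before
    the morning cutoff (default 10:00).
``TIME_GAP``
    (warning) a gap between consecutive meal groups longer than the
    configured maximum (default 6 h).
``IMPLAUSIBLE_PORTION``
    (warning) converted grams for one record exceed the age-class threshold
    (the canonical field example being several cups of cooked rice reported
    for a 13-month-old).
``UNAVAILABLE_FOOD``
    (warning) a food outside the configured regional availability list
    (e.g. strawberries reported in a region where none grow).

Rules are emitted independently; a clean recall yields an empty finding
list.  The module also renders the interviewer's end-of-survey meal summary,
the supervisor's daily report, and per-person dietary profiles — all with
deterministic ordering so reports can be diffed in tests.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from .chrono import group_meals
from .errors import PortionLookupError
from .ingest import PersonDayRecall, format_clock_time
from .portions import PortionDatabase, amount_consumed_g

if TYPE_CHECKING:  # pragma: no cover
    from .fct import FctContext
    from .nutrients import PersonDayIntake

RULE_BF_MISMATCH = "BF_MISMATCH"
RULE_TWO_MORNINGS = "TWO_MORNINGS"
RULE_TIME_GAP = "TIME_GAP"
RULE_IMPLAUSIBLE_PORTION = "IMPLAUSIBLE_PORTION"
RULE_UNAVAILABLE_FOOD = "UNAVAILABLE_FOOD"

RULE_IDS = (
    RULE_BF_MISMATCH,
    RULE_TWO_MORNINGS,
    RULE_TIME_GAP,
    RULE_IMPLAUSIBLE_PORTION,
    RULE_UNAVAILABLE_FOOD,
)

SEVERITY_ERROR = "error"
SEVERITY_WARNING = "warning"


@dataclass(frozen=True, slots=True)
class Finding:
    """One quality-control flag."""

    rule_id: str
    severity: str
    message: str
    entry_refs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule id {self.rule_id!r}")


def _default_portion_max() -> dict[str, float]:
    # max plausible grams per single meal record, by age class; field-report
    # screening thresholds, user-configurable
    return {"infant": 800.0, "child": 1500.0, "adult": 3000.0}


@dataclass
class QCConfig:
    max_gap_minutes: int = 360
    morning_cutoff: int = 600  # minute-of-day, 10:00
    portion_max_g: dict[str, float] = field(default_factory=_default_portion_max)
    availability: frozenset[str] | None = None  # allowed food codes, optional
    grouping_tolerance_minutes: int = 0

    def __post_init__(self) -> None:
        if self.max_gap_minutes <= 0 or self.morning_cutoff <= 0:
            raise ValueError("QC thresholds must be positive")
        for k, v in self.portion_max_g.items():
            if v <= 0:
                raise ValueError(f"portion threshold for {k!r} must be positive")


def age_class(age_months: float) -> str:
    """Age class used by the portion-plausibility table."""
    if age_months < 24:
        return "infant"
    if age_months < 156:  # < 13 y
        return "child"
    return "adult"


def validate_recall(
    recall: PersonDayRecall,
    cfg: QCConfig | None = None,
    *,
    portion_db: PortionDatabase | None = None,
    fct: "FctContext | None" = None,
) -> list[Finding]:
    """Apply all QC rules to one recall; findings are the output, a clean
    recall returns an empty list.

    The portion-plausibility rule needs ``portion_db`` (and ``fct`` for the
    food-group fallback); the availability rule needs ``cfg.availability``.
    Findings are independent of entry file order (they depend on
    ``entry_index`` and times only).
    """
    cfg = cfg or QCConfig()
    findings: list[Finding] = []
    entries = sorted(recall.entries, key=lambda e: e.entry_index)

    # BF_MISMATCH
    n_bf = sum(1 for e in entries if e.is_breastmilk)
    declared = recall.demographics.declared_bf_frequency
    if n_bf != declared:
        findings.append(
            Finding(
                RULE_BF_MISMATCH,
                SEVERITY_ERROR,
                f"declared breastfeeding frequency {declared} but "
                f"{n_bf} breast-milk entries recorded",
                tuple(e.entry_index for e in entries if e.is_breastmilk),
            )
        )

    # TWO_MORNINGS: a time decrease in recorded order with morning times on
    # both sides of the decrease
    times = [e.clock_time for e in entries]
    for i in range(1, len(times)):
        if times[i] < times[i - 1]:
            pre, post = times[:i], times[i:]
            if min(pre) < cfg.morning_cutoff and min(post) < cfg.morning_cutoff:
                findings.append(
                    Finding(
                        RULE_TWO_MORNINGS,
                        SEVERITY_WARNING,
                        "entry times restart before the morning cutoff "
                        f"({format_clock_time(cfg.morning_cutoff)}); recall may "
                        "span two mornings",
                        (entries[i - 1].entry_index, entries[i].entry_index),
                    )
                )
                break

    # TIME_GAP between consecutive meal groups
    groups = group_meals(recall, cfg.grouping_tolerance_minutes)
    for prev, cur in zip(groups, groups[1:]):
        gap = cur.time - prev.time
        if gap > cfg.max_gap_minutes:
            findings.append(
                Finding(
                    RULE_TIME_GAP,
                    SEVERITY_WARNING,
                    f"{gap} min between meals at {format_clock_time(prev.time)} "
                    f"and {format_clock_time(cur.time)} exceeds "
                    f"{cfg.max_gap_minutes} min",
                    (
                        prev.entries[0].entry_index,
                        cur.entries[0].entry_index,
                    ),
                )
            )

    # IMPLAUSIBLE_PORTION (needs gram conversion)
    if portion_db is not None:
        threshold = cfg.portion_max_g.get(age_class(recall.demographics.age_months))
        if threshold is not None:
            for e in entries:
                if e.is_breastmilk:
                    continue
                group = None
                if fct is not None:
                    resolved = fct.resolve(
                        e.food_code, e.description, entry_id=e.entry_id
                    )
                    if resolved.resolved:
                        group = resolved.item.food_group
                try:
                    grams = amount_consumed_g(e, portion_db, food_group=group).grams
                except PortionLookupError:
                    continue
                if grams > threshold:
                    findings.append(
                        Finding(
                            RULE_IMPLAUSIBLE_PORTION,
                            SEVERITY_WARNING,
                            f"{grams:.0f} g in one record exceeds the "
                            f"{threshold:.0f} g plausibility threshold for this "
                            "age class",
                            (e.entry_index,),
                        )
                    )

    # UNAVAILABLE_FOOD
    if cfg.availability is not None:
        for e in entries:
            if e.is_breastmilk:
                continue
            if e.food_code and e.food_code not in cfg.availability:
                findings.append(
                    Finding(
                        RULE_UNAVAILABLE_FOOD,
                        SEVERITY_WARNING,
                        f"food {e.food_code!r} ({e.description}) is outside the "
                        "regional availability list",
                        (e.entry_index,),
                    )
                )

    return findings


# ---------------------------------------------------------------------------
# interviewer's end-of-survey summary
# ---------------------------------------------------------------------------


def interview_summary(
    recall: PersonDayRecall,
    intake: "PersonDayIntake | None" = None,
    cfg: QCConfig | None = None,
    *,
    portion_db: PortionDatabase | None = None,
    fct: "FctContext | None" = None,
) -> str:
    """Plain-text end-of-survey review: each grouped meal with time, items,
    location and portion grams, followed by all QC findings.  Rendering is
    deterministic (ordered by time then entry index)."""
    cfg = cfg or QCConfig()
    grams_by_index: dict[int, float] = {}
    if intake is not None:
        grams_by_index = {m.entry_index: m.grams for m in intake.meals}
    d = recall.demographics
    lines = [
        f"Recall summary for {d.participant_id} on {d.recall_date.isoformat()}",
        f"Day characterization: {d.day_character}; "
        f"declared breastfeeding frequency: {d.declared_bf_frequency}",
    ]
    groups = group_meals(recall, cfg.grouping_tolerance_minutes)
    lines.append(f"Meals recorded: {len(groups)}")
    for g in groups:
        lines.append(
            f"  Meal {g.order} at {format_clock_time(g.time)} "
            f"({', '.join(g.locations)})"
        )
        for e in sorted(g.entries, key=lambda e: e.entry_index):
            if e.is_breastmilk:
                lines.append(f"    - [{e.entry_index}] breast milk")
                continue
            portion = f"{e.portion_count:g} x {e.utensil}/{e.utensil_size}"
            grams = grams_by_index.get(e.entry_index)
            grams_txt = f" = {grams:.0f} g" if grams is not None else ""
            lines.append(
                f"    - [{e.entry_index}] {e.description or e.food_code} "
                f"({portion}{grams_txt})"
            )
    findings = validate_recall(recall, cfg, portion_db=portion_db, fct=fct)
    if findings:
        lines.append("Findings:")
        for f in findings:
            lines.append(f"  {f.severity.upper()} {f.rule_id}: {f.message}")
    else:
        lines.append("Findings: none")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# supervisor's daily report
# ---------------------------------------------------------------------------


def daily_report(
    recalls: Sequence[PersonDayRecall],
    expected_roster: Iterable[str],
    date: dt.date,
    *,
    cfg: QCConfig | None = None,
    top_k: int = 10,
    portion_db: PortionDatabase | None = None,
    fct: "FctContext | None" = None,
) -> dict:
    """Real-time field report for one collection day.

    Contains the missing-form list (roster minus received), the distribution
    of first-meal times, the top-``top_k`` foods per meal-order position, the
    breastfeeding-frequency distribution, and all findings.
    """
    cfg = cfg or QCConfig()
    date_str = date.isoformat()
    todays = [r for r in recalls if r.demographics.recall_date == date]
    received = {r.demographics.participant_id for r in todays}
    missing = sorted(set(expected_roster) - received)

    first_meal_times: list[str] = []
    food_counts_by_order: dict[int, dict[str, int]] = {}
    bf_freq_dist: dict[int, int] = {}
    findings: dict[str, list[dict]] = {}
    for r in sorted(todays, key=lambda r: r.key):
        groups = group_meals(r, cfg.grouping_tolerance_minutes)
        if groups:
            first_meal_times.append(format_clock_time(groups[0].time))
        for g in groups:
            bucket = food_counts_by_order.setdefault(g.order, {})
            for e in g.entries:
                if e.is_breastmilk:
                    continue
                name = e.description or e.food_code
                bucket[name] = bucket.get(name, 0) + 1
        declared = r.demographics.declared_bf_frequency
        bf_freq_dist[declared] = bf_freq_dist.get(declared, 0) + 1
        fs = validate_recall(r, cfg, portion_db=portion_db, fct=fct)
        if fs:
            findings[r.demographics.participant_id] = [
                {"rule_id": f.rule_id, "severity": f.severity, "message": f.message}
                for f in fs
            ]

    top_foods = {
        order: sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        for order, counts in sorted(food_counts_by_order.items())
    }
    return {
        "date": date_str,
        "n_expected": len(set(expected_roster)),
        "n_received": len(received),
        "missing_forms": missing,
        "first_meal_times": sorted(first_meal_times),
        "top_foods_by_meal_order": top_foods,
        "bf_frequency_distribution": dict(sorted(bf_freq_dist.items())),
        "findings": findings,
    }


def render_daily_report(report: dict) -> str:
    lines = [
        f"Daily report for {report['date']}",
        f"Forms received: {report['n_received']}/{report['n_expected']}",
    ]
    if report["missing_forms"]:
        lines.append("Missing forms: " + ", ".join(report["missing_forms"]))
    else:
        lines.append("Missing forms: none")
    lines.append("First-meal times: " + ", ".join(report["first_meal_times"]))
    for order, foods in report["top_foods_by_meal_order"].items():
        lines.append(f"Top foods, meal {order}:")
        for name, count in foods:
            lines.append(f"  {count:4d}  {name}")
    lines.append(
        "Breastfeeding frequency distribution: "
        + ", ".join(f"{k}: {v}" for k, v in report["bf_frequency_distribution"].items())
    )
    if report["findings"]:
        lines.append("Findings:")
        for pid, fs in sorted(report["findings"].items()):
            for f in fs:
                lines.append(f"  {pid}: {f['severity'].upper()} {f['rule_id']}: {f['message']}")
    else:
        lines.append("Findings: none")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# per-person dietary profile
# ---------------------------------------------------------------------------


def dietary_profile(
    recall: PersonDayRecall,
    intake: "PersonDayIntake",
    cfg: QCConfig | None = None,
) -> dict:
    """Machine-readable per-person-day profile: meal timeline with grams and
    energy, daily totals, and QC flags.  Use :func:`render_profile` for the
    plain-text rendering; both are deterministic."""
    cfg = cfg or QCConfig()
    meals_by_index = {m.entry_index: m for m in intake.meals}
    timeline = []
    for g in group_meals(recall, cfg.grouping_tolerance_minutes):
        items = []
        for e in sorted(g.entries, key=lambda e: e.entry_index):
            m = meals_by_index.get(e.entry_index)
            items.append(
                {
                    "entry_index": e.entry_index,
                    "description": (
                        "breast milk" if e.is_breastmilk else (e.description or e.food_code)
                    ),
                    "grams": round(m.grams, 6) if m else 0.0,
                    "energy_kcal": round(m.nutrients.energy_kcal, 6) if m else 0.0,
                    "excluded": m.excluded if m else False,
                }
            )
        timeline.append(
            {
                "time": format_clock_time(g.time),
                "order": g.order,
                "locations": list(g.locations),
                "items": items,
            }
        )
    findings = validate_recall(recall, cfg)
    return {
        "participant_id": recall.demographics.participant_id,
        "recall_date": recall.demographics.recall_date.isoformat(),
        "breastfeeding_entries": sum(1 for e in recall.entries if e.is_breastmilk),
        "meal_frequency_incl_bf": intake.meal_frequency_incl_bf,
        "meal_frequency_excl_bf": intake.meal_frequency_excl_bf,
        "n_unresolved": intake.n_unresolved,
        "timeline": timeline,
        "totals": {k: round(v, 6) for k, v in intake.totals.as_dict().items()},
        "flags": [
            {"rule_id": f.rule_id, "severity": f.severity, "message": f.message}
            for f in findings
        ],
    }


def render_profile(profile: dict) -> str:
    lines = [
        f"Dietary profile: {profile['participant_id']} on {profile['recall_date']}",
        f"Meals (incl/excl breast milk): {profile['meal_frequency_incl_bf']}"
        f"/{profile['meal_frequency_excl_bf']}; "
        f"breast-milk entries: {profile['breastfeeding_entries']}; "
        f"unresolved foods: {profile['n_unresolved']}",
    ]
    for g in profile["timeline"]:
        lines.append(f"  {g['time']} (meal {g['order']}, {', '.join(g['locations'])})")
        for item in g["items"]:
            mark = " [excluded]" if item["excluded"] else ""
            lines.append(
                f"    {item['description']}: {item['grams']:.0f} g, "
                f"{item['energy_kcal']:.0f} kcal{mark}"
            )
    t = profile["totals"]
    lines.append(
        "Daily totals: "
        f"{t['energy_kcal']:.0f} kcal, {t['protein_g']:.1f} g protein "
        f"({t['animal_protein_g']:.1f} g animal), {t['fat_g']:.1f} g fat, "
        f"{t['carb_g']:.1f} g carbohydrate"
    )
    if profile["flags"]:
        for f in profile["flags"]:
            lines.append(f"  FLAG {f['severity'].upper()} {f['rule_id']}: {f['message']}")
    return "\n".join(lines) + "\n"


def profile_json(profile: dict) -> str:
    return json.dumps(profile, sort_keys=True, indent=2)
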