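"""Quality-control rules, interview summaries, daily reports, profiles."""

import random

import pytest

from dietrecall.ingest import PersonDayRecall, parse_clock_time
from dietrecall.nutrients import personday_intake
from dietrecall.quality import (
    QCConfig,
    RULE_BF_MISMATCH,
    RULE_IMPLAUSIBLE_PORTION,
    RULE_TIME_GAP,
    RULE_TWO_MORNINGS,
    RULE_UNAVAILABLE_FOOD,
    age_class,
    daily_report,
    dietary_profile,
    interview_summary,
    render_daily_report,
    render_profile,
    validate_recall,
)

from conftest import DATE, make_demog, make_entry


def recall_with_times(times, pid="P001", bf_flags=None, **demog_kwargs):
    bf_flags = bf_flags or [False] * len(times)
    demog = make_demog(pid=pid, bf=sum(bf_flags), **demog_kwargs)
    entries = [
        make_entry(pid=pid, index=i + 1, time=parse_clock_time(t), bf=flag)
        for i, (t, flag) in enumerate(zip(times, bf_flags))
    ]
    return PersonDayRecall(demographics=demog, entries=entries)


class TestBreastfeedingConsistency:
    def test_matching_declared_and_entered_frequency_is_clean(self):
        # six declared breastfeeds matched by six breast-milk meal entries
        r = recall_with_times(
            ["06:00", "08:00", "10:00", "13:00", "16:00", "19:00"],
            bf_flags=[True] * 6,
        )
        assert validate_recall(r) == []

    def test_mismatch_is_an_error(self):
        r = recall_with_times(
            ["06:00", "08:00", "10:00", "13:00", "16:00"], bf_flags=[True] * 5
        )
        r.demographics.declared_bf_frequency = 6
        findings = validate_recall(r)
        assert [f.rule_id for f in findings] == [RULE_BF_MISMATCH]
        assert findings[0].severity == "error"


class TestTwoMornings:
    def test_restart_before_morning_cutoff_flags(self):
        # 08:00 yesterday through 08:00 today: times decrease and both sides
        # of the decrease contain a morning time
        r = recall_with_times(["08:00", "13:00", "20:00", "08:00"])
        rules = [f.rule_id for f in validate_recall(r)]
        assert RULE_TWO_MORNINGS in rules
        # the 7-h afternoon gap independently trips the gap rule
        assert rules.count(RULE_TWO_MORNINGS) == 1

    def test_monotone_times_do_not_flag(self):
        r = recall_with_times(["08:00", "13:00", "18:30"])
        assert validate_recall(r) == []

    def test_decrease_without_morning_on_both_sides_does_not_flag(self):
        # afternoon re-ordering only: not a two-mornings pattern
        r = recall_with_times(["11:00", "15:00", "13:00", "18:30"])
        assert RULE_TWO_MORNINGS not in {f.rule_id for f in validate_recall(r)}


class TestTimeGap:
    def test_gap_over_threshold_flags_each_occurrence(self):
        r = recall_with_times(["07:00", "14:00", "21:30"])  # gaps 420 and 450
        findings = validate_recall(r)
        assert [f.rule_id for f in findings] == [RULE_TIME_GAP, RULE_TIME_GAP]

    def test_gap_at_threshold_is_clean(self):
        r = recall_with_times(["08:00", "14:00", "19:00"])  # gap exactly 360
        assert validate_recall(r) == []

    def test_custom_threshold(self):
        r = recall_with_times(["08:00", "12:30", "18:30"])
        cfg = QCConfig(max_gap_minutes=240)
        assert [f.rule_id for f in validate_recall(r, cfg)] == [RULE_TIME_GAP, RULE_TIME_GAP]


class TestImplausiblePortion:
    def test_converted_grams_over_age_class_threshold(self, tiny_portion_db, fct_context):
        # 8 plates of ugali for a 13-mo child: 8 x 420 g >> infant threshold
        demog = make_demog(cohort="child", age=13.0, unit="months")
        entries = [make_entry(index=1, time=540, code="T001", portion=8.0)]
        r = PersonDayRecall(demographics=demog, entries=entries)
        findings = validate_recall(r, portion_db=tiny_portion_db, fct=fct_context)
        assert [f.rule_id for f in findings] == [RULE_IMPLAUSIBLE_PORTION]

    def test_same_portion_fine_for_adult(self, tiny_portion_db, fct_context):
        r = PersonDayRecall(
            demographics=make_demog(),
            entries=[make_entry(index=1, time=540, code="T001", portion=2.0)],
        )
        assert validate_recall(r, portion_db=tiny_portion_db, fct=fct_context) == []

    def test_rule_skipped_without_portion_db(self):
        demog = make_demog(cohort="child", age=13.0, unit="months")
        r = PersonDayRecall(
            demographics=demog,
            entries=[make_entry(index=1, time=540, portion=8.0)],
        )
        assert validate_recall(r) == []

    @pytest.mark.parametrize(
        "months,expected", [(13, "infant"), (30, "child"), (492, "adult")]
    )
    def test_age_classes(self, months, expected):
        assert age_class(months) == expected


class TestUnavailableFood:
    def test_food_outside_availability_list_flags(self):
        r = recall_with_times(["09:00", "13:00"])
        cfg = QCConfig(availability=frozenset({"T001"}))
        for e in r.entries:
            e.food_code = "T001"
        r.entries[1].food_code = "STRAWBERRY"
        findings = validate_recall(r, cfg)
        assert [f.rule_id for f in findings] == [RULE_UNAVAILABLE_FOOD]
        assert findings[0].entry_refs == (2,)

    def test_no_list_means_no_rule(self):
        r = recall_with_times(["09:00"])
        r.entries[0].food_code = "ANYTHING"
        assert validate_recall(r) == []


class TestOrderInsensitivity:
    def test_finding_multiset_invariant_under_file_order_permutation(self):
        r = recall_with_times(
            ["08:00", "13:00", "20:30", "08:00", "06:30"],
            bf_flags=[False, False, False, False, True],
        )
        r.demographics.declared_bf_frequency = 3  # also force BF_MISMATCH
        baseline = sorted(f.rule_id for f in validate_recall(r))
        rng = random.Random(0)
        for _ in range(5):
            entries = r.entries[:]
            rng.shuffle(entries)  # file order changes, entry_index preserved
            shuffled = PersonDayRecall(demographics=r.demographics, entries=entries)
            assert sorted(f.rule_id for f in validate_recall(shuffled)) == baseline


class TestInterviewSummary:
    def test_line_per_item_grouped_into_meals(self, simple_recall):
        text = interview_summary(simple_recall)
        assert "Meals recorded: 3" in text
        assert sum(1 for line in text.splitlines() if line.startswith("    - [")) == 3

    def test_empty_recall_states_zero_meals(self):
        r = PersonDayRecall(demographics=make_demog(), entries=[])
        assert "Meals recorded: 0" in interview_summary(r)

    def test_findings_section_present_when_dirty(self):
        r = recall_with_times(["07:00", "14:30"])
        text = interview_summary(r)
        assert "TIME_GAP" in text


class TestDailyReport:
    def _recalls(self):
        return [
            recall_with_times(["08:00", "13:00"], pid=f"P{i}") for i in range(4)
        ]

    def test_missing_form_listed(self):
        report = daily_report(self._recalls(), [f"P{i}" for i in range(5)], DATE)
        assert report["missing_forms"] == ["P4"]
        assert report["n_received"] == 4

    def test_all_received_gives_empty_missing_list(self):
        report = daily_report(self._recalls(), ["P0", "P1", "P2", "P3"], DATE)
        assert report["missing_forms"] == []

    def test_top_k_matches_brute_force_counts(self):
        recalls = []
        foods = ["ugali", "tea", "ugali", "beans", "ugali", "tea"]
        for i, food in enumerate(foods):
            r = recall_with_times(["08:00"], pid=f"P{i}")
            r.entries[0].description = food
            recalls.append(r)
        report = daily_report(recalls, [f"P{i}" for i in range(6)], DATE)
        assert report["top_foods_by_meal_order"][1] == [
            ("ugali", 3), ("tea", 2), ("beans", 1)
        ]
        assert render_daily_report(report)  # renders without error


class TestDietaryProfile:
    def test_profile_totals_equal_nutrient_module_output(
        self, simple_recall, fct_context, tiny_portion_db
    ):
        intake = personday_intake(simple_recall, fct_context, tiny_portion_db)
        profile = dietary_profile(simple_recall, intake)
        assert len(profile["timeline"]) == 3
        assert profile["totals"]["energy_kcal"] == round(
            intake.totals.energy_kcal, 6
        )

    def test_breast_milk_only_recall_has_zero_totals(
        self, fct_context, tiny_portion_db
    ):
        r = recall_with_times(["06:00", "10:00", "15:00"], bf_flags=[True] * 3)
        intake = personday_intake(r, fct_context, tiny_portion_db)
        profile = dietary_profile(r, intake)
        assert all(v == 0.0 for v in profile["totals"].values())
        assert profile["breastfeeding_entries"] == 3

    def test_rerender_is_byte_identical(
        self, simple_recall, fct_context, tiny_portion_db
    ):
        intake = personday_intake(simple_recall, fct_context, tiny_portion_db)
        a = render_profile(dietary_profile(simple_recall, intake))
        b = render_profile(dietary_profile(simple_recall, intake))
        assert a == b
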