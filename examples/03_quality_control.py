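"""Run the quality-control rules and render the field reports.

Shows the breastfeeding-consistency check, the two-mornings heuristic, the
inter-meal gap rule, and the supervisor's daily report.

Run:  python examples/03_quality_control.py
"""

import datetime as dt

from dietrecall import (
    SimConfig,
    daily_report,
    generate_cohort,
    interview_summary,
    render_daily_report,
    validate_recall,
)
from dietrecall.quality import QCConfig

# a cohort with known faults planted: the generator returns the ground truth
cfg = SimConfig(
    n_adults=30,
    n_children=70,
    fault_rates=(("BF_MISMATCH", 0.05), ("TWO_MORNINGS", 0.05), ("TIME_GAP", 0.05)),
)
cohort, ctx, db, _ = generate_cohort(cfg, seed=9)
print(f"planted faults: {len(cohort.faults)}")

n_findings = 0
for r in cohort.recalls:
    findings = validate_recall(r, QCConfig(), portion_db=db, fct=ctx)
    n_findings += len(findings)
print(f"validator findings: {n_findings} "
      "(equals the planted count: clean recalls yield none)")

# the interviewer's end-of-survey summary for one flagged recall
flagged = next(
    r for r in cohort.recalls
    if validate_recall(r, QCConfig(), portion_db=db, fct=ctx)
)
print()
print(interview_summary(flagged, portion_db=db, fct=ctx))

# the supervisor's daily report for the first collection date
date = dt.date.fromisoformat(cfg.base_date)
roster = [r.demographics.participant_id for r in cohort.recalls] + ["MISSING01"]
report = daily_report(cohort.recalls, roster, date, portion_db=db, fct=ctx)
print(render_daily_report(report))
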