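"""Generate a synthetic cohort, write the two-table export, and read it back.

The generator emulates the two study populations (peri-urban adults and
rural children under 2 y) and emits exactly the delimited files the ingest
module consumes.

Run:  python examples/02_simulate_and_ingest.py
"""

import tempfile
from pathlib import Path

from dietrecall import SimConfig, generate_cohort, read_recall_tables

cfg = SimConfig(n_adults=50, n_children=80)
cohort, ctx, portion_db, utensils = generate_cohort(cfg, seed=42)

print(f"generated {len(cohort.recalls)} person-day recalls "
      f"({sum(len(r.entries) for r in cohort.recalls)} meal records)")
print(f"reference utensils: {', '.join(utensils.utensils)}")

with tempfile.TemporaryDirectory() as tmp:
    demog_path, meals_path = cohort.write(Path(tmp))
    recalls = read_recall_tables(demog_path, meals_path)
    print(f"round-tripped {len(recalls)} recalls through the two-table export")

children = [r for r in recalls if r.demographics.cohort == "child"]
breastfed = [r for r in children if r.demographics.declared_bf_frequency > 0]
print(f"children: {len(children)}, of which breastfed yesterday: {len(breastfed)}")
# every declared breastfeed appears as a timed meal entry:
r = breastfed[0]
n_bf = sum(1 for e in r.entries if e.is_breastmilk)
print(f"example child declared {r.demographics.declared_bf_frequency} breastfeeds "
      f"and has {n_bf} breast-milk entries")
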