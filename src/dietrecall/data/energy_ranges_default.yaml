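# Acceptable daily energy-intake ranges (kcal) for young children, used to
# classify a child-day's computed energy as below / within / above.
#
# The breastfed rows are the Dewey-Brown complementary-feeding ranges for
# breastfed children (100-600 kcal at 6-8 mo, 200-750 kcal at 9-11 mo,
# 500-1100 kcal at 12-23 mo).  No defaults are shipped for non-breastfed
# children; add rows with breastfed: false to evaluate them.
energy_ranges:
  - {age_lo_mo: 6, age_hi_mo: 8, breastfed: true, lower_kcal: 100.0, upper_kcal: 600.0}
  - {age_lo_mo: 9, age_hi_mo: 11, breastfed: true, lower_kcal: 200.0, upper_kcal: 750.0}
  - {age_lo_mo: 12, age_hi_mo: 23, breastfed: true, lower_kcal: 500.0, upper_kcal: 1100.0}
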