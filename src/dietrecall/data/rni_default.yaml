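# Default Recommended Nutrient Intake (RNI) table.
#
# Editable reference data, not code.  Rows are matched on nutrient, age band
# (months), sex and bioavailability tier.  Values follow the FAO/WHO (2004)
# vitamin and mineral requirement recommendations commonly used for dietary
# adequacy screening; iron assumes 10% bioavailability and zinc moderate
# bioavailability, the tiers typically applied to plant-based East African
# diets.  The breast-milk-adjusted folate value for 9-11 mo reflects the RNI
# remaining to be met from complementary foods for a breastfed child.
# Replace or extend these rows for other reference systems.
rni:
  # --- children 6-12 mo ---
  - {nutrient: calcium_mg, age_lo_mo: 6, age_hi_mo: 12, sex: any, tier: standard, amount: 400.0}
  - {nutrient: iron_mg, age_lo_mo: 6, age_hi_mo: 12, sex: any, tier: 10pct_bioavailability, amount: 9.3}
  - {nutrient: zinc_mg, age_lo_mo: 6, age_hi_mo: 12, sex: any, tier: moderate_bioavailability, amount: 4.1}
  - {nutrient: vitA_ug_RE, age_lo_mo: 6, age_hi_mo: 12, sex: any, tier: standard, amount: 400.0}
  - {nutrient: folate_ug, age_lo_mo: 6, age_hi_mo: 12, sex: any, tier: standard, amount: 80.0}
  - {nutrient: folate_ug, age_lo_mo: 9, age_hi_mo: 11, sex: any, tier: breast_milk_adjusted, amount: 27.6}
  # --- children 13-36 mo ---
  - {nutrient: calcium_mg, age_lo_mo: 13, age_hi_mo: 36, sex: any, tier: standard, amount: 500.0}
  - {nutrient: iron_mg, age_lo_mo: 13, age_hi_mo: 36, sex: any, tier: 10pct_bioavailability, amount: 5.8}
  - {nutrient: zinc_mg, age_lo_mo: 13, age_hi_mo: 36, sex: any, tier: moderate_bioavailability, amount: 4.1}
  - {nutrient: vitA_ug_RE, age_lo_mo: 13, age_hi_mo: 36, sex: any, tier: standard, amount: 400.0}
  - {nutrient: folate_ug, age_lo_mo: 13, age_hi_mo: 36, sex: any, tier: standard, amount: 150.0}
  # --- adults 19-50 y (228-600 mo) ---
  - {nutrient: calcium_mg, age_lo_mo: 228, age_hi_mo: 600, sex: any, tier: standard, amount: 1000.0}
  - {nutrient: iron_mg, age_lo_mo: 228, age_hi_mo: 600, sex: male, tier: 10pct_bioavailability, amount: 13.7}
  - {nutrient: iron_mg, age_lo_mo: 228, age_hi_mo: 600, sex: female, tier: 10pct_bioavailability, amount: 29.4}
  - {nutrient: zinc_mg, age_lo_mo: 228, age_hi_mo: 600, sex: male, tier: moderate_bioavailability, amount: 7.0}
  - {nutrient: zinc_mg, age_lo_mo: 228, age_hi_mo: 600, sex: female, tier: moderate_bioavailability, amount: 4.9}
  - {nutrient: vitA_ug_RE, age_lo_mo: 228, age_hi_mo: 600, sex: male, tier: standard, amount: 600.0}
  - {nutrient: vitA_ug_RE, age_lo_mo: 228, age_hi_mo: 600, sex: female, tier: standard, amount: 500.0}
  - {nutrient: folate_ug, age_lo_mo: 228, age_hi_mo: 600, sex: any, tier: standard, amount: 400.0}
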