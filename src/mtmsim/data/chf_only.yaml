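# Model configuration: 2019 MTM-eligible adults with congestive heart
# failure (subgroup sensitivity analysis).
#
# Provenance of numeric defaults:
#   effects   — pooled estimates from the 5-study meta-analysis of MTM
#               interventions (fractional reductions with 95% CIs).
#   costs     — screening: published Medicare dietitian-assessment
#               reimbursement range; monthly meal-contract mean calibrated to
#               the published total annual program cost for this population
#               (~$24.8B at 8 months of meals); draw SD calibrated so the
#               program-cost 95% UI half-width is ~7.5% of its mean;
#               per-meal cost: pooled mean (SD) across MTM organizations.
#   population — stratum counts and baseline moments calibrated to published
#               national estimates for 2019 (resolved by name from the
#               package's calibration tables).
population:
  name: chf_only

effects:
  expenditure_reduction: {estimate: 0.197, ci_low: 0.069, ci_high: 0.324}
  hospitalization_reduction: {estimate: 0.470, ci_low: 0.317, ci_high: 0.623}

costs:
  screening_cost_low: 27.34
  screening_cost_high: 35.17
  monthly_meal_cost_mean: 487.60
  monthly_meal_cost_sd: 34.7
  months_of_meals: 8
  per_meal_cost_mean: 9.30
  per_meal_cost_sd: 0.64

engine:
  n_replicates: 1000
  n_records: 50000
  seed: 0
  coverage_fraction: 1.0
  discount_rate: 0.03
  horizon_years: 10
  carryover_fraction: 0.0
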