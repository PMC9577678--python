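study_id,outcome,scale,estimate,ci_low,ci_high,se,n_participants,duration_months
pooled_expenditures,expenditure_pct_change,percent_reduction,0.197,0.069,0.324,,,
pooled_hospitalizations,hospitalization_rr,percent_reduction,0.470,0.317,0.623,,,
pooled_meal_cost,per_meal_cost,usd,9.30,,,,,
pooled_duration,duration_months,months,,,,,1,8
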