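{
 "label": "ARVC 5-year VA risk model (published)",
 "coefficients": {
  "sex_male": 0.488,
  "age_years": -0.022,
  "recent_syncope": 0.657,
  "nsvt_history": 0.811,
  "ln_pvc": 0.170,
  "twi_leads": 0.113,
  "rvef_pct": -0.025
 },
 "s0_table": {
  "1": 0.921,
  "2": 0.876,
  "3": 0.849,
  "4": 0.837,
  "5": 0.801
 }
}
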