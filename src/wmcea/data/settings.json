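{
  "horizon_years": 15,
  "cycles_per_year": 13,
  "discount_rate_effects": 0.03,
  "discount_rate_costs": 0.03,
  "wtp_threshold": 60000.0,
  "start_age": 65,
  "patient": {
    "weight_kg": 75.0,
    "body_surface_area_m2": 1.8
  }
}
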