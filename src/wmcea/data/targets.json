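{
  "_comment": "Published base-case and discount-scenario aggregates used as calibration targets. Costs in EUR (discounted at 3%/year unless noted), life years in years.",
  "life_years_discounted": {"ibrutinib": 6.77, "ctp": 3.77},
  "life_years_undiscounted": {"ibrutinib": 7.80, "ctp": 4.21},
  "cost_components_discounted": {
    "ibrutinib": {"drug": 200461, "administration": 0, "sae": 13423, "post_progression": 19182, "total": 233066},
    "ctp": {"drug": 33835, "administration": 6098, "sae": 21978, "post_progression": 12957, "total": 74868}
  },
  "total_cost_undiscounted": {"ibrutinib": 251779, "ctp": 76157},
  "icers": {"base": 52698, "health_discount_0": 44015, "cost_discount_0": 58503}
}
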