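{
  "pfs_ibrutinib": {
    "family": "weibull",
    "shape": 2.326344583271538,
    "scale": 4.822576711745375
  },
  "post_progression_dwell": {
    "sub1_hazard_per_year": 4.0,
    "sub2_hazard_per_year": 4.0
  },
  "excess_mortality": {
    "ctp_pre_progression_per_year": 0.21024975572059867,
    "bsc_per_year": 0.25134378950379754
  },
  "hazard_ratio": {
    "point": 0.25,
    "ci_low": 0.11,
    "ci_high": 0.57
  },
  "monitoring_costs": {
    "pre_progression_ibrutinib": 60.0,
    "pre_progression_ctp": 2907.288956443584,
    "subsequent": 0.0,
    "bsc": 0.0
  },
  "cost_scales": {
    "ctp_drug": 2.193490357583185,
    "ctp_admin": 1.5587128551930969,
    "post_progression_regimen": 1.4412221528500713,
    "ibrutinib_dose_intensity": 0.7012964663775968
  },
  "sae_rates": {
    "ibrutinib": {
      "neutropenia": 0.027896742331700967,
      "anaemia": 0.01673804539902058,
      "thrombocytopenia": 0.013948371165850484,
      "diarrhoea": 0.01673804539902058,
      "non_pulmonary_infections": 0.013948371165850484,
      "pulmonary_toxicity": 0.0055793484663401935,
      "constipation": 0.0055793484663401935
    },
    "ctp": {
      "neutropenia": 0.1,
      "leucopoenia": 0.05333333333333334,
      "anaemia": 0.06666666666666667,
      "thrombocytopenia": 0.05333333333333334,
      "lymphocytopenia": 0.03333333333333333,
      "non_pulmonary_infections": 0.05333333333333334,
      "neuropathy": 0.04,
      "pulmonary_toxicity": 0.02,
      "constipation": 0.02666666666666667,
      "diarrhoea": 0.03333333333333333
    }
  }
}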