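{
  "_comment": "Default treatment schedules per 4-week model cycle. Schedules are editable configuration assembled from standard Waldenstrom macroglobulinemia regimen references; only unit prices are fixed inputs. Aggregate cost consequences of schedule uncertainty are absorbed by the calibrated cost scales.",
  "regimens": [
    {
      "regimen_id": "ibrutinib",
      "components": [
        {"drug": "ibrutinib", "dose_basis": "mg_per_day", "dose_value": 420, "administrations_per_cycle": 28, "iv_administration": false}
      ],
      "iv_days_per_cycle": 0,
      "max_treatment_cycles": null
    },
    {
      "regimen_id": "FCR",
      "components": [
        {"drug": "fludarabine", "dose_basis": "mg_per_m2", "dose_value": 25, "administrations_per_cycle": 3, "iv_administration": true},
        {"drug": "cyclophosphamide", "dose_basis": "mg_per_m2", "dose_value": 250, "administrations_per_cycle": 3, "iv_administration": true},
        {"drug": "rituximab", "dose_basis": "mg_per_m2", "dose_value": 375, "administrations_per_cycle": 1, "iv_administration": true}
      ],
      "iv_days_per_cycle": 3,
      "max_treatment_cycles": 6
    },
    {
      "regimen_id": "BOR",
      "components": [
        {"drug": "bortezomib", "dose_basis": "mg_per_m2", "dose_value": 1.3, "administrations_per_cycle": 4, "iv_administration": true},
        {"drug": "rituximab", "dose_basis": "mg_per_m2", "dose_value": 375, "administrations_per_cycle": 1, "iv_administration": true}
      ],
      "iv_days_per_cycle": 4,
      "max_treatment_cycles": 6
    },
    {
      "regimen_id": "RCHOP",
      "components": [
        {"drug": "rituximab", "dose_basis": "mg_per_m2", "dose_value": 375, "administrations_per_cycle": 1, "iv_administration": true},
        {"drug": "cyclophosphamide", "dose_basis": "mg_per_m2", "dose_value": 750, "administrations_per_cycle": 1, "iv_administration": true},
        {"drug": "doxorubicin", "dose_basis": "mg_per_m2", "dose_value": 50, "administrations_per_cycle": 1, "iv_administration": true},
        {"drug": "vincristine", "dose_basis": "mg_per_m2", "dose_value": 1.4, "administrations_per_cycle": 1, "iv_administration": true},
        {"drug": "prednisone", "dose_basis": "mg_per_day", "dose_value": 100, "administrations_per_cycle": 5, "iv_administration": false}
      ],
      "iv_days_per_cycle": 1,
      "max_treatment_cycles": 6
    },
    {
      "regimen_id": "BDR",
      "components": [
        {"drug": "bortezomib", "dose_basis": "mg_per_m2", "dose_value": 1.3, "administrations_per_cycle": 4, "iv_administration": true},
        {"drug": "dexamethasone", "dose_basis": "flat_mg", "dose_value": 40, "administrations_per_cycle": 4, "iv_administration": false},
        {"drug": "rituximab", "dose_basis": "mg_per_m2", "dose_value": 375, "administrations_per_cycle": 1, "iv_administration": true}
      ],
      "iv_days_per_cycle": 4,
      "max_treatment_cycles": 6
    },
    {
      "regimen_id": "DRC",
      "components": [
        {"drug": "dexamethasone", "dose_basis": "flat_mg", "dose_value": 20, "administrations_per_cycle": 1, "iv_administration": false},
        {"drug": "rituximab", "dose_basis": "mg_per_m2", "dose_value": 375, "administrations_per_cycle": 1, "iv_administration": true},
        {"drug": "cyclophosphamide", "dose_basis": "mg_per_m2", "dose_value": 200, "administrations_per_cycle": 5, "iv_administration": false}
      ],
      "iv_days_per_cycle": 1,
      "max_treatment_cycles": 6
    },
    {
      "regimen_id": "BR",
      "components": [
        {"drug": "bendamustine", "dose_basis": "mg_per_m2", "dose_value": 90, "administrations_per_cycle": 2, "iv_administration": true},
        {"drug": "rituximab", "dose_basis": "mg_per_m2", "dose_value": 375, "administrations_per_cycle": 1, "iv_administration": true}
      ],
      "iv_days_per_cycle": 2,
      "max_treatment_cycles": 6
    }
  ]
}
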