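{
  "stress_panel": {
    "recA": "K03553",
    "dnaK": "K04043",
    "hsp90": "K04079",
    "clpB": "K03695",
    "clpA": "K03694",
    "clpX": "K03544",
    "groEL": "K04077",
    "rpsA": "K02945",
    "atpD": "K02112"
  },
  "markers": {
    "pmoA": "K10944",
    "hupL": "K06281"
  },
  "sulfur_globule_panel": {
    "tusA": "K04085",
    "dsrA": "K11180",
    "dsrB": "K11181"
  },
  "functional_categories": {
    "sulfur_metabolism": {
      "modules": ["M00176", "M00596", "M00595"],
      "kos": ["K17229", "K17230", "K17218"]
    },
    "methane_metabolism": {
      "modules": ["M00174", "M00346", "M00345", "M00344", "M00140"],
      "kos": ["K00122", "K10713", "K10714", "K01499"]
    },
    "carbon_fixation": {
      "modules": ["M00165", "M00173", "M00579", "M00376", "M00375", "M00374", "M00377", "M00620"],
      "kos": []
    },
    "oxygen_respiration": {
      "modules": ["M00153", "M00417", "M00416", "M00156", "M00157", "M00159"],
      "kos": []
    },
    "nitrogen_metabolism": {
      "modules": ["M00175", "M00531", "M00530", "M00529", "M00804"],
      "kos": []
    },
    "adhesion": {
      "modules": ["M00330"],
      "kos": ["K12549"]
    }
  }
}
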