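{
  "description": "Reference values transcribed from the published group tables of the multicenter iNPH shunt-outcome study this package reanalyzes: exact per-group tap and DESH counts, and the 2-decimal sensitivity/specificity rows of the diagnostic-performance table. These drive the joint 2x2x2 table reconstruction and the fixture cohort.",
  "group_sizes": {"responders": 96, "non_responders": 70},
  "counts": {
    "responders": {"tap_positive": 61, "tap_negative": 35, "desh_positive": 53, "desh_negative": 43},
    "non_responders": {"tap_positive": 28, "tap_negative": 42, "desh_positive": 8, "desh_negative": 62}
  },
  "table4": {
    "tap":       {"sensitivity": 0.64, "specificity": 0.60, "auc": 0.62},
    "desh":      {"sensitivity": 0.55, "specificity": 0.89, "auc": 0.72},
    "ca":        {"sensitivity": 0.45, "specificity": 0.74, "auc": 0.60},
    "tap_desh":  {"sensitivity": 0.79, "specificity": 0.53, "auc": 0.66},
    "tap_ca":    {"sensitivity": 0.85, "specificity": 0.51, "auc": 0.68},
    "majority":  {"sensitivity": 0.77, "specificity": 0.67, "auc": 0.72}
  },
  "ca_cutoff_degrees": 68.7,
  "notes": [
    "The reference narrative reports 10 (tap+DESH) and 16 (tap+CA) additionally identified responders, which is arithmetically inconsistent with the tabulated sensitivities 0.79 and 0.85 at group size 96 (those imply 15 and 21 additional responders over the tap test's 61). The reconstruction trusts the tabulated sensitivities; the discrepancy is surfaced here, not resolved."
  ]
}
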