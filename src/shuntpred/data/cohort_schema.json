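{
  "description": "Column dictionary for shuntpred cohort CSV files. Comma separator, UTF-8, dot decimal, header required; booleans as 0/1; optional fields empty when missing.",
  "columns": {
    "id": {"type": "string", "required": true, "doc": "unique subject identifier"},
    "center_id": {"type": "string", "required": true, "doc": "treating center (one of 3)"},
    "age": {"type": "float", "unit": "years", "required": true, "constraint": "> 0"},
    "sex": {"type": "string", "required": true, "codes": ["male", "female"]},
    "lp_pressure": {"type": "float", "unit": "mmH2O", "required": true, "constraint": "[80, 200] (normal-pressure inclusion window)"},
    "disease_duration": {"type": "float", "unit": "months", "required": true, "constraint": "> 0"},
    "symptom_gait": {"type": "bool01", "required": true, "doc": "gait disturbance present"},
    "symptom_cognitive": {"type": "bool01", "required": true, "doc": "cognitive impairment present"},
    "symptom_urinary": {"type": "bool01", "required": true, "doc": "urinary dysfunction present"},
    "comorb_cardiovascular": {"type": "bool01", "required": true},
    "comorb_endocrine": {"type": "bool01", "required": true},
    "comorb_neurological": {"type": "bool01", "required": true},
    "pre_walk_time": {"type": "float", "unit": "seconds", "required": true, "constraint": "> 0", "doc": "10 m walk time before the tap test"},
    "pre_walk_steps": {"type": "int", "unit": "steps", "required": true, "constraint": "> 0"},
    "pre_mmse": {"type": "int", "required": true, "constraint": "[0, 30]"},
    "pre_urinary": {"type": "int", "required": true, "constraint": "[0, 10]", "doc": "self-rated urinary incontinence severity, 0 normal to 10 severe"},
    "post_walk_time": {"type": "float", "unit": "seconds", "required": true, "constraint": "> 0", "doc": "24-72 h after the tap test"},
    "post_walk_steps": {"type": "int", "unit": "steps", "required": true, "constraint": "> 0"},
    "post_mmse": {"type": "int", "required": true, "constraint": "[0, 30]"},
    "post_urinary": {"type": "int", "required": true, "constraint": "[0, 10]"},
    "ei": {"type": "float", "required": true, "constraint": "(0, 1)", "doc": "Evans index"},
    "desh": {"type": "bool01", "required": true, "doc": "DESH sign (binary visual read)"},
    "ca": {"type": "float", "unit": "degrees", "required": true, "constraint": "(0, 180)", "doc": "callosal angle"},
    "z_ei": {"type": "float", "required": true, "constraint": ">= 0", "doc": "z-Evans index A/B"},
    "bvr": {"type": "float", "required": true, "constraint": ">= 0", "doc": "brain-per-ventricle ratio (B-A)/A"},
    "scca": {"type": "float", "unit": "degrees", "required": true, "constraint": "(0, 180)", "doc": "splenium of corpus callosum angle"},
    "temporal_horn_left": {"type": "float", "unit": "mm", "required": true, "constraint": ">= 0"},
    "temporal_horn_right": {"type": "float", "unit": "mm", "required": true, "constraint": ">= 0"},
    "third_ventricle_width": {"type": "float", "unit": "mm", "required": true, "constraint": ">= 0"},
    "posterior_horn_ratio": {"type": "float", "required": true, "constraint": ">= 0"},
    "preop_severity_score": {"type": "int", "required": true, "constraint": ">= 0", "doc": "symptom severity before surgery (Krauss numerator baseline)"},
    "postop_severity_score": {"type": "int", "required": false, "constraint": ">= 0", "doc": "severity at 6-12 month follow-up; empty before follow-up"},
    "outcome_label": {"type": "string", "required": false, "codes": ["responder", "non_responder"], "doc": "Krauss-rule class; empty before follow-up"}
  }
}
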