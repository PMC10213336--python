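{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "symptomnet cohort CSV dialect",
  "description": "Per-respondent guardian survey record. The CSV is UTF-8 with a header row; one object per row.",
  "type": "object",
  "properties": {
    "respondent_id": {"type": "string"},
    "phq9_1": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_2": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_3": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_4": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_5": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_6": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_7": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_8": {"type": "integer", "minimum": 0, "maximum": 3},
    "phq9_9": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_1": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_2": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_3": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_4": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_5": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_6": {"type": "integer", "minimum": 0, "maximum": 3},
    "gad7_7": {"type": "integer", "minimum": 0, "maximum": 3},
    "fatigue": {"type": "integer", "minimum": 0, "maximum": 10},
    "qol_1": {"type": "integer", "minimum": 1, "maximum": 5},
    "qol_2": {"type": "integer", "minimum": 1, "maximum": 5},
    "age": {"type": "number", "exclusiveMinimum": 0},
    "sex": {"enum": ["male", "female"]},
    "married": {"enum": [0, 1]},
    "employed": {"enum": [0, 1]},
    "rural": {"enum": [0, 1]},
    "physical_disease": {"enum": [0, 1]},
    "visit_difficulty": {"enum": [0, 1]},
    "medication_compliance_good": {"enum": [0, 1]},
    "education": {"enum": ["below_senior", "senior_or_above"]},
    "financial_status": {"enum": ["poor", "fair", "good"]},
    "social_media_freq": {"enum": ["none_minimal", "sometimes", "often"]},
    "diagnosis": {"enum": ["mdd", "bipolar", "schizophrenia", "other"]}
  },
  "required": [
    "phq9_1","phq9_2","phq9_3","phq9_4","phq9_5","phq9_6","phq9_7","phq9_8","phq9_9",
    "gad7_1","gad7_2","gad7_3","gad7_4","gad7_5","gad7_6","gad7_7",
    "fatigue","qol_1","qol_2","age","sex","married","employed","rural",
    "physical_disease","visit_difficulty","medication_compliance_good",
    "education","financial_status","social_media_freq","diagnosis"
  ]
}
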