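{
  "model_id": "CR_POSSUM",
  "family": "score_link",
  "name": "Colorectal POSSUM",
  "citation": "Tekkis PP et al. Development of a dedicated risk-adjustment scoring system for colorectal surgery (colorectal POSSUM). Br J Surg 2004;91:1174-1182.",
  "metadata": {
    "notes": [
      "Category weights frozen as tabulated for external-validation use (leading weight digit per category: urgency 1/3/8, operative severity 1/3/4/8, contamination 1/2/3, heart failure 1/2/3, age 1/3/4/8, staging 1/2/3).",
      "Age-band weights (1/3/4/8) could not be re-verified against the source publication and are frozen as tabulated.",
      "Interval topology: printed integer labels expanded to half-open partitions so every in-range value falls in exactly one bin (e.g. SBP [90,100) carries the '90-99' weight)."
    ],
    "units": {"urea": "mmol/L", "haemoglobin": "g/dL", "sbp": "mmHg", "heart_rate": "beats/min"}
  },
  "groups": {
    "physiological": {
      "age": {
        "field": "age",
        "kind": "numeric",
        "bins": [
          {"label": "<=60", "weight": 1, "intervals": [[null, 60, false, true]]},
          {"label": "61-70", "weight": 3, "intervals": [[60, 70, false, true]]},
          {"label": "71-80", "weight": 4, "intervals": [[70, 80, false, true]]},
          {"label": ">=81", "weight": 8, "intervals": [[80, null, false, false]]}
        ]
      },
      "heart_failure": {
        "field": "heart_failure",
        "kind": "categorical",
        "bins": [
          {"label": "none_or_mild", "weight": 1, "values": ["none_or_mild"]},
          {"label": "moderate", "weight": 2, "values": ["moderate"]},
          {"label": "severe", "weight": 3, "values": ["severe"]}
        ]
      },
      "sbp": {
        "field": "sbp",
        "kind": "numeric",
        "bins": [
          {"label": "100-170", "weight": 1, "intervals": [[100, 170, true, true]]},
          {"label": ">170 or 90-99", "weight": 2, "intervals": [[170, null, false, false], [90, 100, true, false]]},
          {"label": "<90", "weight": 3, "intervals": [[null, 90, false, false]]}
        ]
      },
      "heart_rate": {
        "field": "heart_rate",
        "kind": "numeric",
        "bins": [
          {"label": "40-100", "weight": 1, "intervals": [[40, 100, true, true]]},
          {"label": "101-120", "weight": 2, "intervals": [[100, 120, false, true]]},
          {"label": ">120 or <40", "weight": 3, "intervals": [[120, null, false, false], [null, 40, false, false]]}
        ]
      },
      "urea": {
        "field": "urea",
        "kind": "numeric",
        "bins": [
          {"label": "<=10.0", "weight": 1, "intervals": [[null, 10, false, true]]},
          {"label": "10.1-15.0", "weight": 2, "intervals": [[10, 15, false, true]]},
          {"label": ">15", "weight": 3, "intervals": [[15, null, false, false]]}
        ]
      },
      "haemoglobin": {
        "field": "haemoglobin",
        "kind": "numeric",
        "bins": [
          {"label": "13.0-16.0", "weight": 1, "intervals": [[13, 16, true, true]]},
          {"label": "10.0-12.9 or 16.1-18.0", "weight": 2, "intervals": [[10, 13, true, false], [16, 18, false, true]]},
          {"label": "<10.0 or >18.0", "weight": 3, "intervals": [[null, 10, false, false], [18, null, false, false]]}
        ]
      }
    },
    "operative": {
      "operative_severity": {
        "field": "operative_severity",
        "kind": "categorical",
        "bins": [
          {"label": "minor", "weight": 1, "values": ["minor"]},
          {"label": "moderate", "weight": 3, "values": ["moderate"]},
          {"label": "major", "weight": 4, "values": ["major"]},
          {"label": "complex_major", "weight": 8, "values": ["complex_major"]}
        ]
      },
      "peritoneal_contamination": {
        "field": "peritoneal_contamination",
        "kind": "categorical",
        "bins": [
          {"label": "none_or_serous", "weight": 1, "values": ["none_or_serous"]},
          {"label": "local_pus", "weight": 2, "values": ["local_pus"]},
          {"label": "free_pus_faeces_blood", "weight": 3, "values": ["free_pus_faeces_blood"]}
        ]
      },
      "urgency": {
        "field": "urgency",
        "kind": "categorical",
        "bins": [
          {"label": "scheduled", "weight": 1, "values": ["scheduled"]},
          {"label": "urgent", "weight": 3, "values": ["urgent"]},
          {"label": "emergency", "weight": 8, "values": ["emergency"]}
        ]
      },
      "dukes_stage": {
        "field": "dukes_stage",
        "kind": "categorical",
        "bins": [
          {"label": "A_B", "weight": 1, "values": ["A_B"]},
          {"label": "C", "weight": 2, "values": ["C"]},
          {"label": "D", "weight": 3, "values": ["D"]}
        ]
      }
    }
  },
  "coefficients": {
    "provenance": "original_publication",
    "source_label": "Tekkis 2004 colorectal POSSUM mortality equation",
    "intercept": -9.167,
    "terms": {
      "physiological_score": 0.338,
      "operative_score": 0.308
    }
  }
}
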