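{
  "model_id": "IRCS",
  "family": "category",
  "name": "Identification of Risk in Colorectal Surgery score",
  "citation": "van der Sluis FJ et al. Identification of Risk in Colorectal Surgery (IRCS), 2014 (variable structure).",
  "metadata": {
    "notes": [
      "Five preoperative variables: age band, heart failure, respiratory status, operative urgency, cancer stage.",
      "Category contrasts are kept coarse (binary for heart failure, dyspnoea, and urgency) so a refit remains identifiable in cohorts with ~40 deaths; finer splits separate.",
      "SYNTHETIC coefficient set: the source publication's fitted coefficients are not reproduced here; the shipped values are representative stand-ins on the logit scale (reference = lowest-risk category of each variable) so that the original-coefficient validation path can be exercised end to end. Provenance is tagged synthetic_representative and must not be cited as the published IRCS equation."
    ]
  },
  "groups": {
    "variables": {
      "age": {
        "field": "age",
        "kind": "numeric",
        "bins": [
          {"label": "le60", "weight": 1, "intervals": [[null, 60, false, true]]},
          {"label": "61-70", "weight": 2, "intervals": [[60, 70, false, true]]},
          {"label": "71-80", "weight": 3, "intervals": [[70, 80, false, true]]},
          {"label": "gt80", "weight": 4, "intervals": [[80, null, false, false]]}
        ]
      },
      "heart_failure": {
        "field": "heart_failure",
        "kind": "categorical",
        "bins": [
          {"label": "none_or_mild", "weight": 1, "values": ["none_or_mild"]},
          {"label": "moderate_or_severe", "weight": 2, "values": ["moderate", "severe"]}
        ]
      },
      "respiratory_status": {
        "field": "respiratory_status",
        "kind": "categorical",
        "bins": [
          {"label": "no_dyspnoea", "weight": 1, "values": ["no_dyspnoea"]},
          {"label": "dyspnoea", "weight": 2, "values": ["dyspnoea_on_exertion", "limiting_dyspnoea", "dyspnoea_at_rest"]}
        ]
      },
      "urgency": {
        "field": "urgency",
        "kind": "categorical",
        "bins": [
          {"label": "scheduled", "weight": 1, "values": ["scheduled"]},
          {"label": "non_elective", "weight": 2, "values": ["urgent", "emergency"]}
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
    "provenance": "synthetic_representative",
    "source_label": "Synthetic stand-in coefficients (not the published IRCS fit)",
    "intercept": -5.0,
    "terms": {
      "age:61-70": 0.55,
      "age:71-80": 1.1,
      "age:gt80": 1.7,
      "heart_failure:moderate_or_severe": 0.9,
      "respiratory_status:dyspnoea": 0.6,
      "urgency:non_elective": 1.2,
      "dukes_stage:C": 0.45,
      "dukes_stage:D": 1.15
    }
  }
}
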