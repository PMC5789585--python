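{
  "model_id": "AFC",
  "family": "category",
  "name": "Association Francaise de Chirurgie colorectal mortality score",
  "citation": "Alves A et al. Postoperative mortality and morbidity in French patients undergoing colorectal surgery. Arch Surg 2005;140:278-283.",
  "metadata": {
    "notes": [
      "Four binary risk factors: age > 70 years, neurological comorbidity, weight loss > 10% in 6 months, non-elective (urgent or emergency) surgery.",
      "No original coefficient set is shipped: the source equation is not reproduced in the registry, so external validation with original coefficients is reported as NA; recalibration fits the four indicators afresh."
    ]
  },
  "groups": {
    "variables": {
      "age_over_70": {
        "field": "age",
        "kind": "numeric",
        "bins": [
          {"label": "le70", "weight": 1, "intervals": [[null, 70, false, true]]},
          {"label": "gt70", "weight": 2, "intervals": [[70, null, false, false]]}
        ]
      },
      "neuro_comorbidity": {
        "field": "neuro_comorbidity",
        "kind": "boolean",
        "bins": [
          {"label": "no", "weight": 1, "values": [false]},
          {"label": "yes", "weight": 2, "values": [true]}
        ]
      },
      "weight_loss_gt10pct": {
        "field": "weight_loss_gt10pct",
        "kind": "boolean",
        "bins": [
          {"label": "no", "weight": 1, "values": [false]},
          {"label": "yes", "weight": 2, "values": [true]}
        ]
      },
      "emergency_surgery": {
        "field": "urgency",
        "kind": "categorical",
        "bins": [
          {"label": "no", "weight": 1, "values": ["scheduled"]},
          {"label": "yes", "weight": 2, "values": ["urgent", "emergency"]}
        ]
      }
    }
  },
  "coefficients": null
}
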