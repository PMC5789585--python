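{
  "model_id": "P_POSSUM",
  "family": "score_link",
  "name": "Portsmouth POSSUM",
  "citation": "Prytherch DR, Whiteley MS et al. POSSUM and Portsmouth POSSUM for predicting mortality. Br J Surg 1998;85:1217-1220.",
  "metadata": {
    "notes": [
      "Shares the 18-variable POSSUM binning verbatim (bins_from: POSSUM); only the logistic coefficients differ."
    ]
  },
  "bins_from": "POSSUM",
  "coefficients": {
    "provenance": "original_publication",
    "source_label": "Prytherch 1998 Portsmouth POSSUM mortality equation",
    "intercept": -9.37,
    "terms": {
      "physiological_score": 0.19,
      "operative_score": 0.15
    }
  }
}
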