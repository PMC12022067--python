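{
  "format": "cogdecline-model",
  "version": 1,
  "priors": {
    "brackets": [[30.0, 40.0], [40.0, 45.0], [45.0, 50.0], [50.0, 55.0],
                 [55.0, 60.0], [60.0, 65.0], [65.0, 70.0], [70.0, 75.0],
                 [75.0, 100.0]],
    "n_per_bracket": [9, 7, 31, 27, 41, 43, 40, 19, 11],
    "decliners_per_bracket": [3, 2, 3, 3, 8, 10, 16, 6, 7],
    "overall_n": 228,
    "overall_decliners": 58
  },
  "features": [
    {
      "definition": {
        "name": "stroke_history",
        "source": "stroke",
        "comparator": "flag",
        "hypothesis_sign": 1,
        "hypothesis_group": "cerebrovascular",
        "description": "History of ischemic or hemorrhagic stroke",
        "metadata": {
          "note": "infinite LR+: every symptom carrier declined",
          "training_counts": {"decliners_positive": 3, "decliners": 49,
                              "non_decliners_positive": 0, "non_decliners": 137},
          "validation_counts": {"decliners_positive": 1, "decliners": 9,
                                "non_decliners_positive": 0, "non_decliners": 39}
        }
      },
      "lr_pos": Infinity,
      "lr_neg": 0.94,
      "role": "risk"
    },
    {
      "definition": {
        "name": "fainting",
        "source": "scopa_16",
        "comparator": "gt",
        "cutoff": 0,
        "hypothesis_sign": 1,
        "hypothesis_group": "hypoperfusion",
        "description": "Fainting in the past 6 months (SCOPA-AUT 16)"
      },
      "lr_pos": 2.80,
      "lr_neg": 0.97,
      "role": "risk"
    },
    {
      "definition": {
        "name": "dream_vocalization",
        "source": "rbdsq_6_1",
        "comparator": "flag",
        "hypothesis_sign": 1,
        "hypothesis_group": "rbd",
        "description": "Speaking, shouting, swearing or laughing loudly during dreams (RBDSQ 6.1)"
      },
      "lr_pos": 2.70,
      "lr_neg": 0.56,
      "role": "risk"
    }
  ],
  "decision_cutoff": 0.5,
  "provenance": {
    "note": "four-question screening model: age of onset (bracket prior), history of stroke, fainting in the past 6 months, vocalization during dreams"
  }
}
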