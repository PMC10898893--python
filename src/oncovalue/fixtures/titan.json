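{
  "schema": "oncovalue-trial/1",
  "trial_name": "TITAN",
  "test_label": "apalutamide + ADT",
  "comparator_label": "placebo + ADT",
  "efficacy": {
    "death_hr": {"point": 0.67, "ci_low": 0.51, "ci_high": 0.89, "endpoint": "overall_survival"}
  },
  "toxicity_test": {"precomputed_total": 44.5},
  "toxicity_comparator": {"precomputed_total": 40.0},
  "bonus": {
    "palliation_significant": true,
    "qol_significant": false,
    "notes": {
      "tail": "No tail-of-curve points: the time point at twice the placebo median was not reached.",
      "palliation": "Statistically significant prolongation of median time to pain deterioration and related pain outcomes; 10 points.",
      "qol": "No statistically significant differences in FACT-P, BPI-SF or EQ-5D-5L overall or domain scores; 0 points.",
      "tfi": "Not reported."
    }
  },
  "metadata": {}
}
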