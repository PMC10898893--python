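{
  "schema": "oncovalue-trial/1",
  "trial_name": "ARCHES",
  "test_label": "enzalutamide + ADT",
  "comparator_label": "placebo + ADT",
  "efficacy": {
    "death_hr": {"point": 0.66, "ci_low": 0.53, "ci_high": 0.81, "endpoint": "overall_survival"}
  },
  "toxicity_test": {"precomputed_total": 49.5},
  "toxicity_comparator": {"precomputed_total": 45.0},
  "bonus": {
    "palliation_significant": true,
    "qol_significant": true,
    "notes": {
      "tail": "No tail-of-curve points: the time point at twice the placebo median was not reached.",
      "palliation": "Delay of first symptomatic musculoskeletal event, HR 0.52 (95% CI 0.33-0.80); 10 points.",
      "qol": "Significant delay of first clinically meaningful deterioration in worst pain, pain severity and EQ-5D-5L visual analogue scale; 10 points.",
      "tfi": "Not reported."
    }
  },
  "metadata": {}
}
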