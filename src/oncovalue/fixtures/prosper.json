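{
  "schema": "oncovalue-trial/1",
  "trial_name": "PROSPER",
  "test_label": "enzalutamide + ADT",
  "comparator_label": "placebo + ADT",
  "efficacy": {
    "death_hr": {"point": 0.73, "ci_low": 0.61, "ci_high": 0.89, "endpoint": "overall_survival"}
  },
  "toxicity_test": {"precomputed_total": 49.5},
  "toxicity_comparator": {"precomputed_total": 38.0},
  "reported_toxicity_score": -4.64,
  "bonus": {
    "tail": {
      "comparator_median": 14.7,
      "assessment_time": 29.4,
      "prop_test": 0.45,
      "prop_comparator": 0.3,
      "awarded_points": 16.0
    },
    "palliation_significant": false,
    "qol_significant": true,
    "notes": {
      "tail": "Metastasis-free proportion 50% greater than control at 29.4 months; 16 tail-of-curve points awarded. The curve proportions themselves are not published: prop_test/prop_comparator are synthetic representative values consistent with the reported >=50% improvement.",
      "qol": "FACT-P social and family well-being subdomain: mean least-square difference 0.94 (95% CI 0.02-1.85), p = 0.045; overall FACT-P and EQ-5D-5L not significant.",
      "palliation": "No improvement in cancer-related symptoms evident; 0 points.",
      "tfi": "Treatment-free interval data not available."
    }
  },
  "metadata": {
    "toxicity_inconsistency": "Published point totals 49.5 (test) vs 38 (comparator) give a formula score of -6.05, but the published scorecard and NHB use -4.64. Both are stored; choose via toxicity_source.",
    "nhb_note": "Published NHB 48.36 (scorecard and results text); the abstract prints 48.33. 48.36 = 27 - 4.64 + 26 is the internally consistent value."
  }
}
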