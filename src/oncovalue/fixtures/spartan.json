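{
  "schema": "oncovalue-trial/1",
  "trial_name": "SPARTAN",
  "test_label": "apalutamide + ADT",
  "comparator_label": "placebo + ADT",
  "efficacy": {
    "death_hr": {"point": 0.78, "ci_low": 0.64, "ci_high": 0.96, "endpoint": "overall_survival"}
  },
  "toxicity_test": {"precomputed_total": 27.0},
  "toxicity_comparator": {"precomputed_total": 22.0},
  "bonus": {
    "tail": {
      "comparator_median": 16.2,
      "assessment_time": 32.4,
      "prop_test": 0.45,
      "prop_comparator": 0.3,
      "awarded_points": 16.0
    },
    "qol_significant": false,
    "notes": {
      "tail": "Metastasis-free proportion 50% higher than control at 32.4 months; 16 tail-of-curve points awarded. Curve proportions are not published: prop_test/prop_comparator are synthetic representative values consistent with the reported >=50% improvement.",
      "qol": "Quality of life similar between groups throughout; FACT-P and EQ-5D-3L showed no significant differences in overall scores or domains.",
      "palliation": "Not reported.",
      "tfi": "Not reported."
    }
  },
  "metadata": {
    "os_ci_note": "The results prose prints the OS CI as (0.23-0.35); the published scorecard prints (0.64-0.96), which is the interval consistent with HR 0.78 and is used here."
  }
}
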