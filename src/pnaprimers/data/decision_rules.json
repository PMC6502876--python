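{
  "comment": "Decision-tree rule table for PCR-based PNA study design. Kept as data so the wiring can be reviewed and diffed. Branches with an empty guidance list have no explicit recommendation in the source framework and are deliberately not guessed.",
  "method_by_quantity": {
    "relative": "16S-amplicon-sequencing",
    "absolute": "qPCR"
  },
  "guidance_by_intent": {
    "compare_with_other_studies": [
      "use-identical-primer-pairs-as-reference-study"
    ],
    "characterize_dynamics": [
      "evaluate-candidate-primers-with-in-silico-coverage",
      "interpret-results-relative-to-a-reference-sample-from-the-same-reactor"
    ]
  },
  "guidance_by_question": {
    "presence": [],
    "richness": [],
    "evenness": []
  },
  "always_required_checks": [
    "in-silico-coverage-analysis"
  ],
  "gel_check": {
    "code": "gel-electrophoresis-product-verification",
    "omit_for_degenerate_primers": true
  },
  "warnings": {
    "normalization_to_total_eub": "normalization-of-group-abundances-to-total-eubacteria-is-strongly-discouraged"
  }
}
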