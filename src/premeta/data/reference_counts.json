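{
  "description": "Published nine-category marker counts from a genome-wide comparison of prediagnostic and clinical-stage CLL blood expression markers (11,904-gene common universe; 15,613 genes analyzed in the prediagnostic arm).",
  "universe": 11904,
  "clinical_bonferroni_total": 116,
  "prediag_bonferroni_total": 535,
  "concordant_grid": {
    "up": {
      "bonferroni_both": 1,
      "prediag_bonf_clinical_nominal": 106,
      "clinical_bonf_prediag_nominal": 6,
      "nominal_both": 284
    },
    "down": {
      "bonferroni_both": 8,
      "prediag_bonf_clinical_nominal": 62,
      "clinical_bonf_prediag_nominal": 55,
      "nominal_both": 576
    }
  },
  "prediag_exclusive": 192,
  "clinical_exclusive": 41,
  "dissimilar": {
    "minus_plus": 7,
    "plus_minus": 25
  }
}
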