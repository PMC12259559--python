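{
  "table2_cohort": {
    "expression": "table2_expression.tsv",
    "subjects": "table2_subjects.tsv",
    "description": "Self-collected plasma RT-qPCR cohort: 6 genes x 50 subjects (32 sepsis incl. 11 septic shock, 18 healthy controls); relative gene copy counts vs beta-actin."
  },
  "table4_panels": {
    "file": "table4_panels.json",
    "description": "Published max-logistic classifier coefficients per cohort."
  },
  "table1_meta": {
    "file": "table1_meta.json",
    "description": "Cohort metadata for the 11 discovery/validation cohorts plus the PBMC cohort."
  },
  "pbmc_panels": {
    "file": "pbmc_panels.json",
    "description": "PBMC (GSE9960) max-logistic classifiers on an LN(x+1) scale."
  }
}
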