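[
  {"cohort_id": "GSE65682", "accession": "GSE65682", "tissue": "whole_blood",
   "population": "US adult cohort", "n_case": 761, "n_control": 41},
  {"cohort_id": "GSE28750", "accession": "GSE28750", "tissue": "whole_blood",
   "population": "Australian adult cohort", "n_case": 21, "n_control": 20},
  {"cohort_id": "GSE57065", "accession": "GSE57065", "tissue": "whole_blood",
   "population": "French adult cohort", "n_case": 82, "n_control": 25},
  {"cohort_id": "GSE95233", "accession": "GSE95233", "tissue": "whole_blood",
   "population": "French adult cohort", "n_case": 102, "n_control": 22},
  {"cohort_id": "GSE69528", "accession": "GSE69528", "tissue": "whole_blood",
   "population": "US and Thai adult cohort", "n_case": 83, "n_control": 55},
  {"cohort_id": "GSE131761", "accession": "GSE131761", "tissue": "whole_blood",
   "population": "Spanish adult cohort", "n_case": 81, "n_control": 15},
  {"cohort_id": "GSE154918", "accession": "GSE154918", "tissue": "whole_blood",
   "population": "Australian and German adult cohort", "n_case": 65, "n_control": 40,
   "severity_split": {"septic_shock": 19, "sepsis": 20}},
  {"cohort_id": "GSE13904", "accession": "GSE13904", "tissue": "whole_blood",
   "population": "US children cohort", "n_case": 209, "n_control": 18},
  {"cohort_id": "GSE9692", "accession": "GSE9692", "tissue": "whole_blood",
   "population": "US children cohort", "n_case": 45, "n_control": 15},
  {"cohort_id": "GSE49757", "accession": "GSE49757", "tissue": "plasma",
   "population": "US adult cohort", "n_case": 37, "n_control": 19,
   "severity_split": {"severe_sepsis": 20, "sepsis": 15}},
  {"cohort_id": "selfcollected", "accession": "self-collected", "tissue": "plasma",
   "population": "Chinese adult cohort", "n_case": 32, "n_control": 18,
   "severity_split": {"septic_shock": 11, "sepsis": 21}},
  {"cohort_id": "GSE9960", "accession": "GSE9960", "tissue": "pbmc",
   "population": "Australian cohort", "n_case": 54, "n_control": 16}
]
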