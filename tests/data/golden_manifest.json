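{
 "candidates": {
  "n_candidates": 20,
  "n_failed_consistency": 26,
  "n_failed_expression": 0,
  "n_failed_fdr": 180,
  "n_input": 200
 },
 "de": {
  "n_aging_degs": 20,
  "n_filtered_all_zero": 0,
  "n_tested": 200
 },
 "normalize": {
  "common_dispersion": 0.041064
 },
 "responsive": {
  "n_responsive": 1
 },
 "scores": {
  "common_top_genes": [
   "g00003",
   "g00014",
   "g00019",
   "g00033",
   "g00042",
   "g00050",
   "g00051",
   "g00058",
   "g00061",
   "g00065",
   "g00074",
   "g00078",
   "g00082",
   "g00086",
   "g00141",
   "g00148",
   "g00152",
   "g00167",
   "g00183",
   "g00196"
  ],
  "n_scored": 20
 },
 "truth_recovery": {
  "false_candidates": 0,
  "n_candidates_planted": 20,
  "n_planted_aging": 20
 }
}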