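subjects_path: null
icd_path: null
genotypes_path: null
cohort_subjects_path: null
cohort_icd_path: null
locus_list_path: null
catalog_path: null
simulate:
  n_subtypes: 5
  derivation_cases_per_subtype: 300
  cohort_cases_per_subtype: 200
  cohort_controls: 3000
  p_high: 0.8
  p_low: 0.05
  n_cluster_features: 17
  strata:
  - - EUR
    - 0.7
  - - AFR
    - 0.3
  n_lead_snps: 39
  n_tag_snps: 5
  tag_flip: 0.1
  global_or: 1.5
  subtype_or: 1.8
  maf_range:
  - 0.1
  - 0.5
  icd_sensitivity: 1.0
min_prevalence: 0.05
r2_min: 0.1
ld_window: 500000
bonferroni_n: 39
gw_alpha: 5.0e-08
methods:
- spectral
- kmeans
- hierarchical
- dbscan
k_min: 2
k_max: 20
affinity_neighbors: 10
dbscan_eps: 1.5
dbscan_min_samples: 5
linkage: average
n_restarts: 10
knn_k: 3
n_pcs: 4
beta_method: onestep
n_negative_controls: 5
seeds:
  simulate: 11
  cluster: 13
  negative_control: 15
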