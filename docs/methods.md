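# Methods

## Problem setting and model

The pipeline treats an ICD-coded EHR cohort as a case-control study with
latent disease subtypes. Cases are females carrying any ICD-9 `617*` or
ICD-10 `N80*` code (prefix matching on uppercased, dot-stripped codes;
all other females are controls). Each case is represented by binary
"ever-coded" clinical flags — no dates, counts or severity — because
billing histories are the one signal reliably shared across health
systems. Subtypes are assumed to express themselves as distinct joint
prevalence patterns over those flags, and genetic effects are allowed to
differ by subtype; the package's purpose is to recover the subtypes
without supervision and measure the power gained by testing candidate
loci within them.

## Synthetic cohort generator

The generator is the package's substitute for access-controlled biobank
data and defines the study conditions under which everything is
validated.

* **Subjects.** Exact configured counts: `n_controls` controls and
  `n_cases_per_subtype[k]` cases per subtype k (case-control
  ascertainment, not forward simulation, so stratified analyses always
  have their planned sample sizes). Ages are N(50, 13²) clipped to
  [18, 90]; ancestry labels are drawn per subject from configured stratum
  fractions (default EUR 0.7 / AFR 0.3).
* **Features.** Conditionally independent given the subtype: flag j is
  Bernoulli(p_jk) for subtype-k cases, Bernoulli(p_j0) for controls. The
  default planted structure (`block_prevalence`) assigns each of 17
  features an elevated prevalence 0.8 in exactly one subtype (j mod K)
  and 0.05 elsewhere — strong separation, chosen so that recovery
  failures indicate implementation defects rather than an unidentifiable
  model. Real cohorts have correlated features; conditional independence
  is a declared simplification, so passing tests demonstrate correctness
  of the machinery, not that real EHR data cluster this cleanly.
* **Genotypes.** Controls are Hardy–Weinberg draws Binomial(2, maf).
  Cases of subtype k draw genotype g ∈ {0,1,2} with probability
  ∝ HWE(g)·exp(β_k g), the case-conditional distribution implied by a
  logistic disease model — the retrospective-sampling identity that makes
  the planted log odds ratio β_k the estimand of the downstream logistic
  regression. The implied case allele frequency
  Σ_g (g/2)HWE(g)e^{β_k g} / Σ_g HWE(g)e^{β_k g}
  (= 0.3913 at maf 0.3, β = log 1.5) is the closed-form oracle used in
  tests. LD is simulated by copying a lead variant's genotypes and
  re-drawing each subject from HWE with probability `tag_flip`
  (so r ≈ 1 − tag_flip); per-stratum maf overrides create genuine
  between-ancestry heterogeneity for the meta-analysis.
* **ICD emission.** Every positive flag emits one code (the feature's
  first ICD-10 prefix), kept with probability `icd_sensitivity`
  (default 1.0, making extraction the exact inverse of emission — a
  round-trip identity the tests exploit). Cases additionally emit a bare
  `N80`, which triggers the case rule without colliding with the
  four-character anatomical-site prefixes; control feature rows for
  anatomical sites are forced to zero since those codes would otherwise
  convert controls into cases.

## Feature catalog

The default catalog has 39 entries partitioned 9 (anatomical sites,
ICD-9 617.0–617.9 / ICD-10 N80.0–N80.9) / 14 comorbidities / 8 symptoms
/ 8 pregnancy phenotypes, with plausible ICD-9/ICD-10 prefixes for the
named conditions (migraine G43, irritable bowel K58, fibromyalgia M79.7,
leiomyoma D25, dysmenorrhea N94.6, infertility N97, ...). Coding
practice varies across sites, so the catalog is data, not code: it
round-trips through YAML and any entry can be replaced. Anatomical sites
never enter clustering (they are near-tautological with case status) and
are re-introduced as extra flags during characterization. The clustering
panel keeps non-anatomical features with prevalence among cases
≥ `min_prevalence` (default 0.05, closed threshold).

## Clustering engine

* **Affinity.** Symmetrized k-nearest-neighbor connectivity graph
  (default 10 neighbors) under Manhattan distance, which on binary flags
  is the Hamming count; all points tied with the k-th neighbor distance
  are included, so duplicated rows — common in binary data — form
  complete subgraphs rather than arbitrary partial ones.
* **Spectral clustering.** Top-K eigenvectors of D⁻¹ᐟ²AD⁻¹ᐟ² (the bottom
  of the symmetric normalized Laplacian), dense divide-and-conquer
  eigensolver up to n = 1500 and Lanczos (`eigsh`, largest-algebraic)
  above; rows normalized to unit length; cluster assignment by
  column-pivoted QR of Uᵀ (the K pivot rows act as cluster
  representatives, each subject joining the representative with largest
  |inner product|), falling back to seeded best-of-10 k-means in
  eigenspace when the QR representatives are near-collinear or leave a
  cluster empty. When the affinity graph has exactly K connected
  components this reproduces the components exactly — the oracle
  equivalence tested against `scipy.sparse.csgraph`.
* **Baselines.** k-means (k-means++ init, 10 restarts, best SSE, ties to
  the earliest restart), agglomerative clustering (average linkage on
  Manhattan by default; ward switches to Euclidean as it must), and a
  plain density-reachability DBSCAN (Manhattan radius queries via
  cKDTree); DBSCAN infers its own cluster count and reports all-noise as
  `n_clusters_found = 0` rather than raising.
* **Metrics.** Manhattan silhouette (noise excluded, singleton members
  scored 0); distortion = within-cluster SSE to Euclidean centroids
  (centroid-based by definition, hence Euclidean even though the
  silhouette is Manhattan); evenness = (largest − smallest cluster)/n,
  minimized. All metrics are invariant to relabeling and row permutation.
* **Model selection.** The sweep covers K = 2–20 per method (DBSCAN
  contributes its single inferred row; the affinity graph, its
  eigenvectors and the distance matrix are computed once per sweep).
  Selection is codified so it is testable: (1) drop methods whose
  inferred cluster count falls outside [2, 20] on every row; (2) rank
  survivors by mean evenness; (3) walking that ranking, select the first
  method whose distortion curve has a strict interior local minimum,
  taking the smallest such K; (4) if none has one, take the maximum
  silhouette row. A visual elbow judgment is replaced by the strict
  local-minimum rule deliberately — on strongly separated data splitting
  a true cluster at K+1 *raises* spectral SSE, which is exactly the
  interior minimum the rule detects.

## Characterization

Cluster-vs-rest pooled two-proportion z-tests per feature (plus any
extra flags, e.g. anatomical sites or chart-review variables, through
the same code path). z² equals the Pearson chi-square of the 2×2 table —
asserted on every emitted row in tests. Degenerate tables (pooled
proportion 0 or 1, or an empty side) are flagged, never reported as
z = 0. Significance defaults to Bonferroni over all feature × cluster
tests; the correction is configurable because annotation conventions
differ.

## Label transfer

A k = 3 nearest-neighbor classifier on the clustering features
(Manhattan distance), trained on the derivation cohort's final labels.
Binary features make exact ties routine, so the rules are explicit:
every training point tied with the k-th neighbor distance votes; a vote
tie goes to the single nearest neighbor (smallest distance, then
smallest training index). Test subjects missing a feature column are an
error; subjects with no codes simply have all-zero rows (never-coded
semantics).

## Association testing

* **Locus panel.** Lead SNPs are expanded with tags on the same
  chromosome at strict distance < 500 kb and r² > 0.1, where r² is the
  squared Pearson correlation of mean-imputed dosages in a reference
  genotype matrix (the cohort's controls stand in for an external panel
  in the synthetic runs); r² is symmetric and allele-flip invariant.
  Monomorphic leads yield lead-only loci with a warning.
* **Score test.** Per ancestry × dataset stratum, the null logistic
  model `case ~ 1 + age + PCs` is fitted once (statsmodels); each
  variant is then tested by the efficient score U = gᵀ(y−μ̂) with
  variance V = gᵀWg − gᵀWX(XᵀWX)⁻¹XᵀWg, U²/V ~ χ²₁ — the same
  null-model-once, score-per-variant design that large-scale mixed-model
  tools use, minus the relatedness matrix (the synthetic cohorts have no
  kinship; this substitution is deliberate and logged). Effect estimates
  default to the one-step U/V with se 1/√V; `beta_method="full"` refits
  by maximum likelihood per variant for unbiased effect sizes, and an
  optional Lugannani–Rice saddlepoint tail replaces the normal
  approximation under severe case:control imbalance.
* **Covariates.** Age plus the first 4 principal components of the
  frequency-standardized dosage matrix, computed within each stratum
  from an LD-pruned panel (greedy r² ≤ 0.2). Pruning matters at
  candidate-locus scale: a correlated tag pair is a dominant PCA
  eigenvector, and unpruned PCs would absorb the very association signal
  under test. With fewer polymorphic variants than requested PCs the
  count degrades gracefully. Missing dosages are mean-imputed per
  variant; variants monomorphic after imputation are skipped with a
  recorded reason.
* **Strata.** Cases are one cluster's members in the stratum; controls
  are the stratum's non-endometriosis females, shared across phenotypes.
  Strata with fewer than `min_stratum_cases` (default 5) cases are
  skipped.

## Meta-analysis and controls

DerSimonian–Laird random effects: Q = Σw(β−β_FE)², w = 1/se²,
τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)), RE weights 1/(se²+τ²). Whenever
Q ≤ k−1 the estimate collapses exactly to the fixed-effect
inverse-variance meta — a tested identity. A single stratum passes
through unchanged. Random effects are the default because ancestry
strata are genuinely heterogeneous (the generator can plant per-stratum
allele frequencies to exercise this).

The positive control pools all cases. The negative control permutes the
multiset of cluster labels across cases, per dataset, so every
negative-control analysis has exactly the real analysis' case and
control counts; it carries the *pooled* (diluted) signal, so planted
loci may legitimately reach significance there with reduced strength —
only calibration on null loci is a correctness claim. Locus-level
significance is the minimum p over lead + tags with no per-locus
multiplicity adjustment (candidate-locus convention), compared strictly
against 5×10⁻⁸ and 0.05/39.

## Numerical and design choices

* Seeds: one integer per stochastic stage (`simulate`, `cluster`,
  `negative_control`); identical config + seeds give byte-identical
  artifacts, asserted end-to-end.
* The dense spectral eigensolver is numpy's `eigh` (divide-and-conquer):
  LAPACK's default RRR driver sporadically fails on affinity matrices
  with many duplicated rows.
* k-means ties across restarts resolve to the earliest restart; QR
  assignment degeneracy is detected via the pivoted R diagonal
  (ratio < 1e-8).
* Positions are 1-based (VCF convention) everywhere; LD windows use
  strict inequalities, as do both significance thresholds.
* Dataset enters as a stratum (ancestry × dataset cells are
  meta-analyzed) rather than as a batch covariate.
* The stratified-power property is validated with the generator's planted
  subtype labels rather than re-clustered labels, isolating the
  association/meta machinery from clustering noise; subtype recovery is
  validated separately.

## Validation scale and limitations

Tests and the acceptance script use 2,500-case derivation cohorts
(500 per subtype) for recovery, 1,000 cases / 5,000 controls for
calibration (2,000 null variants), 100 replicates for effect-size and
power properties, and 10 × 39 × 5 meta tests for negative-control
calibration — sizes chosen as the package's own desk-scale conditions.
Known limitations: no kinship/relatedness modeling (hence no GRM in the
test), conditionally independent features given subtype, binary-only
features, no longitudinal structure, LD limited to lead-tag pairs, and
spectral ARI on the strong-separation generator varies ≈ 0.88–0.95
across generator seeds — the variability of the simulated data, not of
the deterministic clustering.
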