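# Methods

This note documents the models and procedures implemented in `brainmodes`,
the numerical conventions chosen where more than one reasonable option
exists, and what the synthetic-data generator does and does not emulate.

## Data model and preprocessing

The pipeline consumes a subjects × IDPs matrix `W` of imaging-derived
phenotypes with an explicit missingness mask, a subjects × confounds table,
a subjects × nIDPs table of non-imaging variables, and (optionally) a
genotype dosage panel with a variant map. Preprocessing runs in a fixed
order:

1. **Outlier removal.** Per IDP column, entries further than `k = 6` median
   absolute deviations from the median are set missing. The MAD is
   unscaled (no 1.4826 Gaussian consistency factor): for Gaussian data the
   fence sits at ≈ 4.05 σ, a deliberately permissive rule that only trips
   on gross artefacts. Columns with MAD exactly 0 flag nothing (with a
   warning) — deleting constant-but-valid columns would be worse than
   keeping them.
2. **Quantile normalisation.** Each column is replaced by inverse-normal
   scores of its ranks using Blom offsets, `Φ⁻¹((r − 3/8)/(n + 1/4))`, with
   average ranks on ties. Columns become approximately standard Gaussian;
   rank order is preserved exactly.
3. **Subject exclusion.** Subjects missing 50 or more IDPs (counted after
   outlier removal) are dropped.
4. **Noise fill.** Remaining missing cells are replaced by N(0, 0.01²)
   draws — negligible against unit-variance columns, but enough to avoid
   degenerate zero-variance patterns downstream.
5. **Deconfounding.** Confounds (plus an intercept, always) are regressed
   out of every column. Age-derived confound columns are *excluded* on the
   IDP pathway (age signal must survive into mode discovery) and *included*
   on the nIDP pathway. For nIDPs each confound is additionally
   sex-separated (zeroed outside each sex) before regression, so variables
   existing in only one sex stay numerically stable. Rank-deficient
   designs fall back to the pseudoinverse with a warning.

## Mode discovery

Each population mode is a rank-1 term: an IDP-weight vector (the ICA
source, sparse and heavy-tailed across IDPs) times a subject-weight vector.
Because the data are far more non-Gaussian along the IDP dimension than the
subject dimension, ICA estimates independence across IDPs.

* **Age weighting.** Before decomposition, column *i* is rescaled by
  `0.1 + |corr(age, Wᵢ)|`, focusing the subsequent PCA+ICA on age-related
  covariation while the 0.1 floor keeps age-orthogonal structure
  estimable. Zero-variance columns receive the floor weight.
* **PCA + FastICA.** The column-demeaned matrix is reduced by SVD to *d*
  principal components; FastICA (tanh contrast, symmetric decorrelation,
  tolerance 1e-6, max 1000 iterations, up to 5 seeded restarts on
  non-convergence) rotates the IDP-space coordinates into independent
  source vectors. Subject weights follow from the mixing matrix.
* **Split-half reproducibility.** Per split, ICA runs on the full sample
  and on two random half-samples; half-run components are paired to the
  full run greedily on |corr| of IDP-weight vectors (repeatedly fix the
  globally largest remaining entry). A component is reproducible when both
  paired half components exceed |r| = 0.9. The per-dimensionality score is
  the mean count over 10 random splits; the sweep picks the dimensionality
  maximising it, breaking ties toward the larger value. An
  optimal-assignment pairing (`method="hungarian"`) is available for
  sensitivity checks; ICA non-convergence in a split counts that split as
  zero rather than aborting, since non-identifiable (Gaussian-only) data is
  exactly what the reproducibility filter should reject.
* **Finalisation.** At the chosen dimensionality the split-half evaluation
  reruns 30 times; the run with the highest reproducible count wins (ties:
  first encountered) and only its reproducible full-data components are
  retained. Subject weights are then recomputed by projecting the
  *deconfounded, unweighted* matrix onto the pseudoinverse of the retained
  IDP weights, so age weighting shapes discovery only, never downstream
  statistics. Modes are sign-flipped so subject weights correlate
  non-negatively with age, and ordered by decreasing variance explained by
  a cubic age model.
* **Null calibrations.** Two Monte-Carlo simulations quantify chance
  levels: (a) the maximum |corr| between one random 62-sample vector and
  128 independent random vectors, accumulated over 10⁶ repetitions (its
  90th percentile sits near 0.41 and its overall maximum near 0.68 — far
  below the 0.9 retention bar); (b) the maximum |corr| between a random
  probe of length 18,707 and 128 independent null subject-weight vectors
  over 100 repeats (≈ 0.032). The second simulation exploits that null
  subject-weight vectors are independent of the probe, so independent
  Gaussian vectors are distributionally equivalent.
* **Pseudo-IDP reduction.** For compact display, each modality group's
  modes × IDPs block is PCA-reduced to the smallest dimensionality
  explaining 90% of block variance (capped at 10) and ICA-rotated;
  components whose maximum |weight| falls below half the strongest
  component's are dropped, but every group keeps at least one pseudo-IDP.
  A single-component reduction uses the dominant SVD axis directly (ICA
  has nothing to rotate).

## Mode clustering

The same age-weighted matrix is re-decomposed at dimensionalities 2–50 (a
smaller range at desk scale). Candidate dimensionality *d* is scored by
how cleanly each high-dimensional mode associates with a single cluster:
per mode, the strongest minus the second-strongest |corr| between its
subject-weight vector and the *d* cluster subject-weight vectors, summed
over modes (for d = 1 the second-strongest is defined as 0). The cost is
a raw sum — only the argmax matters — and ties break toward larger *d*.
Clusters are oriented and ordered exactly as modes are; each mode is
assigned to its highest-|corr| cluster.

## Brain-age delta

Step 1 regresses age on the modes' demeaned subject-weight matrix:
`Y = Xβ₁ − δ₁`, so `δ₁ = Xβ₁ − Y` is predicted-minus-actual age (positive
= older-appearing). Step 2 residualises δ₁ on `Y₂ = [age, age², age³,
confounds]`, removing the age-dependent bias of the first step: `δ₁ = Y₂β₂
+ δ₂`. Both steps are linear, so the per-mode split `δ₁ᵢ = Xᵢβ₁ᵢ − aY`
(with the arbitrary share `a = 1/N_modes`; its value cancels in step 2)
and the per-mode residuals δ₂ᵢ satisfy `Σᵢ δ₁ᵢ = δ₁` and `Σᵢ δ₂ᵢ = δ₂`
exactly. All regressions demean and carry an intercept, so deltas are
mean-zero after step 2.

* **Partialled deltas** (and, identically, partialled subject weights):
  mode *i*'s vector residualised on all other modes' vectors — its unique
  variance.
* **Age curves.** A cubic fit for quantitative use, plus model-free
  sliding-window means (width 5 y around 1-y bin centres; bins under 10
  subjects suppressed) computed for all subjects and per sex. For
  sex-separated curves, subject weights should be recomputed from a
  deconfounded matrix that retains sex.
* **Non-additive test.** Whether the *scale* of delta changes over the age
  range: |δ₂| is regressed on demeaned age; slope, t and two-sided p are
  reported. This |δ|-vs-age convention is the package's choice of
  estimator for scale trends; it is simple, calibrated (type-I ≈ 0.05
  under homoscedastic nulls), and positive slopes mean delta grows with
  age.
* **All-in-one delta.** All IDPs reduced to 55 principal-component scores
  (configurable) entering the same two-step model as the "modes"; at full
  rank this reproduces the direct two-step fit exactly.

## Association scan

Deltas (raw or partialled) are Pearson-correlated with every preprocessed
nIDP on pairwise-complete observations — never imputed — for all subjects
and per sex. Variables with fewer than 40 observations in a subgroup are
skipped. Two-sided p uses the t transform with n − 2 degrees of freedom;
the df lost to prior deconfounding is ignored (the confound count is tiny
against the sample sizes in scope). −log10 p is capped at 320 for output
stability. A (phenotype, variable) pair is reported when *any* subgroup
reaches −log10 p > 5, annotated against Bonferroni reference thresholds
(7.0 for a 62-mode family, 6.0 for a 6-cluster family).

## Desk-scale GWAS

Variants are kept when MAF ≥ 0.01, imputation info ≥ 0.3 and
Hardy-Weinberg equilibrium p ≥ 1e-7 (chi-square with 1 df from genotype
counts — appropriate at the large per-variant counts in scope; info is
consumed as metadata, never recomputed from dosages). Subjects split
randomly (seed-reproducible) into disjoint discovery and replication
cohorts, discovery fraction 2/3 by default, mirroring the 10,612 / 5,340
proportions of a full-scale study. Per variant, the delta is regressed on
dosage with covariates and an intercept (covariates are projected out of
both sides once; df = n − n_cov − 2); monomorphic or covariate-collinear
dosages yield flagged, undefined rows excluded from peaks.

Peak clumping follows the iterative rule exactly: seed the set with every
variant at −log10 p ≥ threshold (7.5 single-GWAS, 9.33 = 7.5 + log10(68)
after Bonferroni adjustment across 62 + 6 phenotypes); repeatedly report
the most significant remaining variant and delete all set members within
0.25 cM of it on the same chromosome (closed interval; cross-chromosome
distance is infinite; exact ties break toward the earlier variant in the
map). A discovery peak validates in replication when its two-sided p <
0.05 *and* the effect sign agrees — the sign condition is standard practice
added as a documented convention.

## Synthetic data

The generator emulates the *structure* of a population imaging study, not
its content: data = Σₖ (subject weights)ₖ ⊗ (IDP weights)ₖ + confound
contamination + N(0, σ²) noise, with missing cells, and outliers planted at
8–12 column SDs (guaranteed to trip the 6-MAD fence). Subject weights
follow configurable linear/quadratic/cubic age profiles plus unit
idiosyncratic noise over a 45–80 y uniform age range; IDP weights are
sparse Laplace (zero with probability 1 − sparsity), which gives ICA its
non-Gaussian identifiability. Confounds (head size, sex, motion, table
position, site, smooth scan-date drift) contaminate linearly with random
per-IDP loadings.

Defaults are 1000 subjects × 200 IDPs, 5 modes, sparsity 0.1, mode
strength 4 (rank-1 amplitude in units of the noise SD), noise SD 1,
missing rate 0.01, outlier rate 0.002. These were chosen once so the
planted modes are *strong* — per-mode eigenvalues an order of magnitude
above the noise bulk, the regime the reproducibility machinery is designed
to certify. At this scale, recovery of planted IDP-weight vectors
typically lands at |r| ≈ 0.90–0.99; the binding limit is ICA estimation
variance with only 200 IDP samples per weight vector (quantile
normalisation also compresses the highest-signal columns, which is why
ever-stronger planted modes stop improving recovery). Denser or weaker
modes drop recovery toward the high 0.8s — below the pipeline's own
retention bar — so passing tests certify behaviour under clearly-present
structure, not performance on marginal real-world modes.

Genotypes: two latent Gaussian haplotype processes per subject, AR(1)
across variants within LD blocks (adjacent-variant latent correlation
`exp(−Δcm/0.05)`, blocks 0.1 cM, positions on a uniform 1 cM/Mb map),
thresholded at the target allele frequency — so Hardy-Weinberg holds by
construction and MAF/genotype counts are recorded from the realised data.
Causal variants are drawn at MAF ≥ 0.1 (passing QC by construction) and
add `effect × (dosage − mean)` to the target mode's subject weights.
nIDPs with a planted correlation r to a mode's delta are built as
`r·standardised delta + √(1−r²)·noise`, with random missingness and an
optional variable observed in exactly 39 subjects (just under the
association scan's inclusion rule).

Not emulated: MRI physics or acquisition artefacts, realistic human LD
maps or recombination hotspots, relatedness/population structure,
non-linear confound effects, and informative (non-random) missingness.
Conclusions from passing tests are therefore about the estimators'
correctness and calibration, not about effect sizes in real cohorts.

## Problem sizes and determinism

Shipped defaults keep a full discovery-to-GWAS run at seconds on one core:
the dimensionality sweep covers 4–10 at 10 splits; finalisation uses 30
reruns; the cluster sweep covers 2–7; GWAS panels are hundreds of variants.
The two null calibrations run at their full published sizes (10⁶ and 100
repetitions) in the acceptance script, and at 10⁵ repetitions in the test
suite, which estimates the same 90th percentile to well within Monte-Carlo
error. Every stochastic step takes an explicit seed and is bit-reproducible
given it; FastICA restarts derive their seeds deterministically from the
caller's.
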