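# brainmodes

Population brain aging is not one process. Given a large cohort's
imaging-derived phenotypes (IDPs — scalar summaries of brain structure and
function from multimodal MRI), `brainmodes` decomposes the subjects × IDPs
matrix into multiple **modes** of population covariation, estimates a
**bias-corrected brain-age delta** for each mode, and scans those deltas
against non-imaging variables and genotypes. It is written for
biostatisticians and imaging-genetics researchers who want the full chain —
preprocessing, data-driven mode discovery with reproducibility control,
delta modelling, association testing and a desk-scale GWAS — as tested,
seed-reproducible library code, exercised end to end on synthetic cohorts
with planted ground truth.

## The model

Each mode *k* is a rank-1 term of the data matrix `W` (subjects × IDPs):
an ICA source vector of IDP weights and a paired subject-weight vector.
Columns of `W` are cleaned (6 × MAD outlier removal, rank-based inverse
normal transformation, subject exclusion at ≥ 50 missing IDPs, N(0, 0.01²)
noise fill, confound regression), rescaled by the age-relatedness factor
`0.1 + |corr(age, Wᵢ)|`, and decomposed by PCA + FastICA. Components are
kept only when split-half reproducible: paired greedily to half-sample
ICA runs by |corr| of IDP-weight vectors and retained at |r| > 0.9, with
the PCA dimensionality chosen to maximise the mean reproducible count over
10 random splits. Two Monte-Carlo null simulations calibrate that bar:
chance pairing correlations reach only ≈ 0.41 at the 90th percentile
(maximum ≈ 0.68 in 10⁶ trials), and a random probe substituted for age
yields subject-weight correlations of at most ≈ 0.032.

Brain-age delta is the two-step estimate

    Y = Xβ₁ − δ₁          (age on subject weights; δ₁ ⊥ X)
    δ₁ = Y₂β₂ + δ₂        (Y₂ = [age, age², age³, confounds]; δ₂ ⊥ Y₂)

with exact per-mode decompositions `δ₁ᵢ = Xᵢβ₁ᵢ − aY`, `Σᵢδ₂ᵢ = δ₂`, and
partialled variants isolating each mode's unique variance. Downstream,
deltas are Pearson-correlated with non-imaging variables (pairwise
complete, n ≥ 40, sex-separated variants) and regressed on variant dosages
(MAF/info/HWE QC, discovery/replication split, iterative 0.25 cM peak
clumping at −log10 p thresholds 7.5 and 9.33).

## Worked example

A complete synthetic study at the default scale (1000 subjects × 200 IDPs,
5 planted modes, 500 variants in LD blocks with two causal effects,
100 nIDPs with two planted correlations):

```python
import numpy as np
from brainmodes.simulate import (SimulationConfig, GenotypeConfig, NIDPConfig,
    generate_idp_dataset, generate_genotypes, generate_nidps, genetic_mode_offsets)
from brainmodes.preprocess import preprocess_idps
from brainmodes.modes import age_weight, sweep_dimensionality, finalize_modes
from brainmodes.containers import AgeDesign
from brainmodes.delta import fit_deltas

panel, causal = generate_genotypes(GenotypeConfig(
    n_subjects=1000, n_variants=500, causal=((50, 0, 0.6), (300, 2, 0.6)), rng_seed=2))
matrix, confounds, age, truth = generate_idp_dataset(
    SimulationConfig(rng_seed=1), subject_weight_offsets=genetic_mode_offsets(panel, causal, 5))

dense, clean, dropped = preprocess_idps(matrix, confounds, rng_seed=1)
weighted, _ = age_weight(dense, age)
report = sweep_dimensionality(weighted, range(4, 11), n_splits=10, rng_seed=1)
modes = finalize_modes(weighted, dense, report.chosen_dim, age, n_runs=30, rng_seed=1)
deltas = fit_deltas(modes.subject_weights, AgeDesign(age))
```

This prints, step by step:

```
reproducibility counts: {4: 3.8, 5: 5.0, 6: 5.0, 7: 5.0, 8: 4.9, 9: 4.6, 10: 4.4} -> chosen dim 7
n modes: 5   recovery vs planted IDP weights: [0.980 0.928 0.975 0.936 0.918]
mean abs delta: 3.378 y
```

The sweep finds that PCA dimensionality 7 supports five reproducible
components (higher dimensionalities start admitting non-reproducible
noise components); all five planted modes are recovered at |r| > 0.9, and
the combined modes predict age to a mean absolute delta of ≈ 3.4 years at
the shipped signal-to-noise. Scanning the per-mode deltas against the
nIDPs reports exactly the two planted pairs (r = 0.30 at −log10 p ≈ 18.9,
r = 0.20 at ≈ 8.9), and the GWAS recovers both planted loci as clumped
peaks that replicate (discovery −log10 p ≈ 25.2 and 17.5, replication
p < 1e-11, sign-concordant) with no false peaks among the 500 variants.
Note that discovered modes are renumbered by decreasing age dependence, so
a planted mode's index and its discovered label generally differ.

The same pipeline is scriptable from a shell via the `brainmodes` CLI
(`simulate`, `preprocess`, `modes`, `null`, `clusters`, `delta`, `assoc`,
`gwas` subcommands; see `brainmodes --help`).

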