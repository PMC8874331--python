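# cranioshape

Geometric morphometrics of coordinated brain–skull development.

`cranioshape` is a Python toolkit for asking whether two anatomical
structures — typically the brain (landmarked on µMRI) and the skull
(landmarked on µCT) of the same animals — develop in a coordinated way, and
whether a genotype or a treatment disturbs that coordination.  It was built
for longitudinal mouse studies (e.g. the Ts65Dn Down-syndrome model with and
without a green-tea-extract intervention, followed at postnatal days 3, 14
and 29), but every component works on any landmark dataset.

## What it computes

Given per-specimen landmark configurations (TPS files or long-format CSV):

* **Generalized Procrustes Analysis (GPA).** Configurations are centered,
  scaled to unit centroid size and iteratively rotated to a consensus,
  leaving pure shape coordinates.  Only proper rotations are used —
  anatomical landmarks are chirally meaningful.
* **Morphospace.** PCA of the Procrustes coordinates (covariance matrix,
  divisor *n* − 1); shapes along a component are reconstructed as
  mean + score · axis.  Derived linear measures (cephalic index = width /
  length, olfactory-bulb and cerebellum lengths) come from raw physical
  coordinates, with per-stage landmark overrides.
* **Group inference.** The shape difference between groups is the
  Procrustes distance between group mean shapes,
  d = √Σᵢ‖p̄₁ᵢ − p̄₂ᵢ‖², tested by permuting group labels with
  p = (b + 1)/(N + 1); for small samples the label partitions are
  enumerated exhaustively.  Per-individual *deviance* is a specimen's
  Procrustes distance to the reference (wild-type untreated) consensus, and
  brain vs skull deviances are correlated per group.
* **Integration (two-block PLS).** SVD of the inter-block covariance matrix
  C = X₁ᵀX₂/(n − 1) yields paired axes ordered by covariation; the Pearson
  correlation of paired axis scores and the RV coefficient
  RV = tr(S₁₂S₂₁)/√(tr(S₁₁²)·tr(S₂₂²)) quantify the magnitude of
  integration, with permutation p-values under the null of complete
  independence between blocks (re-pairing specimens).
* **Developmental statistics.** Mann–Whitney tests (exact for small
  samples), Benjamini–Hochberg discovery screening, a univariate
  ROUT-style robust outlier screen, Mantel–Haenszel logrank tests on the
  first day a developmental milestone appears, and cumulative-incidence
  curves with binomial SEM.
* **Synthetic cohorts.** A generator with per-group mean-shape offsets,
  stage growth, isotropic landmark noise and a shared latent factor whose
  strength ρ tunes brain–skull covariation — with ground truth recorded, so
  every estimator can be validated by parameter recovery.

## Worked example

```python
import cranioshape as cs
from cranioshape.simulate import default_config, simulate_shape_cohort

cfg = default_config(seed=1)          # 4 groups, 3 stages, rho = 1
cohort = simulate_shape_cohort(cfg)
brain = cs.gpa(cohort.sample_set("brain", "PD14"))
skull = cs.gpa(cohort.sample_set("skull", "PD14"))

pc = cs.pca(brain)
print(f"PC1+PC2 variance: {pc.percent_variance[:2].sum():.2f}%")

test = cs.permutation_test_distance(brain, "WT", "TS", n_permutations=9999, seed=1)
print(f"WT vs TS mean-shape distance: {test.observed_statistic:.4f} (p = {test.p_value:.4f})")

pls = cs.two_block_pls(brain, skull)
p_sv = cs.pls_permutation_test(pls, n_permutations=999, seed=1)
print(f"PLS1 correlation: {pls.axis_correlations[0]:.2f}, RV = {pls.rv:.2f} (p = {p_sv.p_value:.4f})")

lr = cs.logrank_test(cohort.milestones, "WT", "TS", milestone="incisor_eruption")
print(f"incisor eruption logrank: chi2 = {lr.statistic:.2f}, p = {lr.p_value:.4f}")
```

prints

```
PC1+PC2 variance: 64.57%
WT vs TS mean-shape distance: 0.0108 (p = 0.4628)
PLS1 correlation: 0.97, RV = 0.93 (p = 0.0010)
incisor eruption logrank: chi2 = 11.16, p = 0.0008
```

Reading the numbers: the first two principal components carry 64.6 % of the
shape variance of this simulated brain sample; the trisomic-vs-wild-type
mean-shape difference at PD14 is not separable from the landmark noise at
these group sizes (permutation p ≈ 0.46); the brain and skull blocks are
strongly integrated (first-axis correlation 0.97, RV 0.93, permutation
p = 0.001, as built into the generator at ρ = 1); and the simulated 2-day
delay in incisor eruption of the trisomic group is clearly detected by the
logrank test.

The same analyses run from the shell:

```sh
cranioshape simulate --seed 1 --out cohort/
cranioshape compare cohort/landmarks_brain_PD14.csv --group-a WT --group-b TS
cranioshape pls cohort/landmarks_brain_PD14.csv cohort/landmarks_skull_PD14.csv
cranioshape run-all --seed 1 --n-perm 999 --out report/
cranioshape dose --concentration 0.33 --intake 6 --mass 20
```

`run-all` writes tidy CSV tables (GPA summary, PCA eigenvalues and scores,
pairwise distances with permutation p-values, deviance tables and
correlations, PLS summaries and scores, trait and milestone tests) plus a
manifest with the config hash and all seeds; a rerun with the same config is
bit-identical.

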