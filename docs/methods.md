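# Methods

This note documents the statistical models and procedures implemented in
`cranioshape`, the numerical conventions that make results reproducible, and
what the synthetic-data generator does and does not emulate.

## Shape model and superimposition

A specimen is an ordered configuration of k landmarks in d ∈ {2, 3}
dimensions (mm).  Landmark order is semantic: index i is the same anatomical
locus on every specimen of a structure and stage.  Size is the centroid size
CS = √Σᵢ‖pᵢ − p̄‖²; shape is what remains after removing location, size and
orientation.

**Generalized Procrustes Analysis.** Every configuration is centered and
scaled to CS = 1, rotated to the first specimen as the initial reference,
then repeatedly rotated to the running consensus (the arithmetic mean shape
rescaled to unit centroid size) until the consensus moves by less than the
tolerance (default 1e-10 in consensus root-sum-of-squares) or the iteration
cap (default 500) is reached.  Scaling is fixed at unit centroid size
throughout; rotations are the SVD solution of the cross-product matrix with
a determinant correction so that reflections are never absorbed (flipping
the axis of the smallest singular value).  The summed squared residual about
the mean is non-increasing across iterations: each rotation step minimizes
distance to the current mean, and replacing the mean can only lower the sum
of squares.  Convergence is linear; highly dispersed samples (shape
variation far beyond anything a landmarking study produces) converge with a
ratio near 0.85 per iteration, which is why the cap is 500 rather than a
few dozen — iterations cost one small SVD per specimen.

After convergence the whole solution is rotated so the consensus lies along
its principal axes, with column signs fixed deterministically (the
largest-magnitude loading of each leading axis positive, flips applied in
pairs to keep the rotation proper).  This canonical orientation makes the
returned frame independent of specimen input order; order invariance is
verified by test rather than assumed.

Downstream statistics operate on the aligned coordinates directly.  No
explicit tangent-space projection is applied: the shape variation handled
here is small (Procrustes distances ≪ 1), where the curvature correction is
far below the landmark noise.  This choice is recorded so results are
reproducible; a projection variant is deliberately out of scope.

**Pairwise superimposition.** `align_pair` centers both configurations,
rotates the moving one by the optimal proper rotation and scales it by the
least-squares-optimal factor (which is non-negative by construction, since
the determinant-corrected alignment trace is σ₁ + |…| ≥ 0).  The
`procrustes_distance` metric has two modes: `fixed` (root summed squared
landmark differences in a shared frame — the metric used for group
comparisons and deviance scores) and `optimal` (both shapes reduced to unit
centroid-size preshapes, rotation and scale optimized; the minimized
distance is √(1 − t²) with t the alignment trace, hence symmetric).  Note
√(1 − t²) loses half the floating-point digits as t → 1, so near-identical
shapes have a distance floor around 1e-8.

## Morphospace

PCA is computed on the covariance matrix (divisor n − 1) of flattened
aligned coordinates via SVD of the centered data.  Superimposition leaves a
similarity null space (7 dimensions for 3D data, 4 for 2D); components with
eigenvalue ≤ 1e-12 × the leading eigenvalue are dropped as numerical noise.
Axis signs are fixed so the largest-magnitude loading is positive.  Scores
have exactly zero column means and diagonal covariance equal to the
eigenvalues; reconstruction from all retained components reproduces each
specimen to ~1e-9.

Derived measures (cephalic index = distance(4,5)/distance(1,3), with the
denominator pair (1,11) at PD3 where the early-stage landmarking scheme
differs; olfactory-bulb length = distance(1,2); cerebellum length =
distance(10,3)) are computed on raw physical coordinates, because lengths
are reported in mm; ratios are identical under either coordinate choice.

## Group inference

The difference between two groups is the fixed-frame Procrustes distance
between their mean shapes inside the joint superimposition of all specimens
of that structure and stage.  The superimposition is label-blind, so it is
*not* recomputed per permutation — the permutation null is exact either way
and this is orders of magnitude faster.

Permutation p-values use the Monte-Carlo convention p = (b + 1)/(N + 1),
which counts the observed statistic as one draw of the null, guarantees
validity, and bounds p below by 1/(N + 1).  The default is N = 10,000; when
the number of distinct label partitions C(n, n₁) is at most 20,000 the null
is enumerated completely instead and p is exact.  The two group labels are
canonicalized internally so the p-value is invariant to argument order.

Deviance is a specimen's fixed-frame distance to the reference-group
consensus (reference specimens included — their spread measures normal
intra-group variation).  Per-group Pearson correlations of brain vs skull
deviances use the t-distribution with n − 2 df; groups with fewer than
3 paired specimens or zero variance are reported as not computable rather
than dropped silently.

## Two-block PLS and RV

Each block is superimposed by its own separate GPA (the two structures come
from different imaging modalities and are landmarked independently), then
column-centered.  The SVD of C = X₁ᵀX₂/(n − 1) gives paired axes ordered by
singular value; percent covariance is σᵢ²/Σσ².  The axes are orthonormal
within each block and distinct axis pairs share no covariation
(U᷈ᵢᵀC Vⱼ = σᵢδᵢⱼ); within-block score columns are *not* mutually orthogonal
— that property belongs to PCA, not two-block PLS.  Block-1 axis signs are
fixed by the largest-loading convention; the first block-2 axis is flipped
if needed so the first axis correlation is non-negative.

RV = tr(S₁₂S₂₁)/√(tr(S₁₁²)·tr(S₂₂²)) is computed via Frobenius norms
(tr(S₁₂S₂₁) = ‖S₁₂‖²_F).  It is invariant under orthogonal transformations
within a block and reduces to the squared Pearson correlation for 1-D
blocks.  RV is upward-biased at small n (of order √(p₁p₂)/n under
independence), as is the first-axis score correlation — at n = 25 with
30- and 60-dimensional blocks the independence baseline of the axis-1
correlation is near 0.9.  Recovery tests therefore validate *monotone
response* to the generating strength and axis collinearity, not absolute
calibration of these descriptive statistics; the permutation tests, which
compare against the re-pairing null, are calibrated regardless of the bias.

Permutation inference re-pairs the rows of block 2 against block 1
(statistic: first singular value by default; RV and the first-axis
correlation are also available), with the same (b + 1)/(N + 1) convention.
Per-group analyses subset the pairs to one group before PLS, because
group-specific correlations are the quantity of interest; pooled-axis
projection is available as an alternative.  Group covariation patterns are
compared by standardized major-axis slopes of block-2 on block-1 scores,
sign(r)·sd(y)/sd(x), which is exactly 1 when block 2 duplicates block 1.

## Univariate and milestone statistics

* **Mann–Whitney** (two-sided): exact null enumeration when the combined
  sample size is ≤ 12 and there are no ties — the regime of these
  experimental groups, where exactness matters — otherwise the normal
  approximation with tie and continuity corrections (delegated to scipy).
* **Benjamini–Hochberg**: textbook step-up rule; flags never fewer
  hypotheses than Bonferroni at the same level.
* **ROUT-style outlier screen**: the univariate (constant-model) reduction
  of the robust-fit + FDR procedure — robust center = median, spread =
  1.4826 × MAD (falling back to 1.2533 × mean absolute deviation when over
  half the values sit at the median), two-sided t-tail p-values of the
  standardized residuals screened by BH at the stated maximum FDR Q.  The
  full nonlinear-regression form is out of scope because the screened
  quantities are single measurement groups.
* **Logrank (Mantel–Haenszel)** on the first day a milestone appears:
  observed-minus-expected events summed over distinct event days with
  hypergeometric variance terms; (O − E)²/V is χ² with 1 df.  Animals whose
  milestone never appeared by the last test day (PD15 by default) are
  censored there; the censoring is visible in the records so it can be
  audited.  Identical event-day multisets in equal-sized groups give
  statistic 0 and p = 1 by construction.
* **Cumulative incidence**: per-day percent achieved with binomial SEM
  √(p̂(1 − p̂)/n) × 100.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume:

* **Groups and stages.** Defaults: WT 12, TS 8, WT-treated 13, TS-treated 9
  (the earliest-stage imaging cohort sizes); stages PD3/PD14/PD29 with
  growth multipliers 1.0/1.4/1.6 applied to the template.
* **Templates.** Brain: 10 hand-placed landmarks on an idealized pup brain
  (half-axes 8 × 6 × 5 mm); ventricles: 9 landmarks on a midsagittal 2D
  profile — both counts as used in the motivating study; skull: 20
  landmarks over an idealized vault and base (the anatomical skull list is
  configurable; 20 is a plausible placeholder density).
* **Noise.** Isotropic Gaussian landmark noise, SD 0.1 mm (brain, skull)
  and 0.05 mm (ventricles) — realistic digitizing error for structures of
  this size, and the simplest exchangeable error model that exercises every
  downstream statistic.
* **Group effects.** Deformation directions (trisomic brachycephaly:
  shorter antero-posterior, wider medio-lateral; treatment: dorso-ventral
  flattening) are projected orthogonal to the similarity directions
  (translations, scaling, rotation generators at the template) so that
  superimposition cannot absorb them, then scaled in units of the noise SD
  (TS offsets 2–3×, treatment 1.5×; the skull effect is stronger than the
  brain effect, mirroring skull-first dysmorphology).
* **Integration.** One standard-normal latent factor z per specimen and
  stage enters every 3D structure as ρ · noise_sd · √(k·d) · z · loading
  with unit-norm loadings, shared across structures.  ρ is therefore the
  per-coordinate RMS displacement of the shared factor relative to the
  noise: at ρ = 1 integration and noise move each coordinate equally hard.
  Estimated RV and first-axis correlation respond monotonically to ρ, and
  at ρ = 4 the recovered first axis is collinear with the generating
  loading (cosine ≥ 0.95 after rotating the loading into the aligned
  frame).
* **Milestones.** First-appearance days are integer-rounded normal draws
  around group-shifted baselines (delays concentrated on incisor eruption,
  eye opening and tactile orientation in the trisomic group), censored past
  PD15.
* **Determinism.** One global seed expands into independent substreams
  (shapes, milestones, traits, ground-truth Monte Carlo) via seed-sequence
  spawning, so adding one component never perturbs another's draws.

What the generator does **not** emulate: anisotropic or landmark-specific
digitizing error, litter effects and longitudinal within-animal
correlation across stages, allometric shape–size covariation, and
non-Gaussian shape variation.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data features.

`true_rv` provides the pseudo-population RV at a configured ρ from one
large single-group raw-coordinate sample (n ≥ 10⁴) with a block-bootstrap
standard error.  Under independence the RV does not reach 0 at finite n —
it carries a positive O(√(p₁p₂)/n) bias that dominates the bootstrap SE —
so the independence check asserts a small absolute value that shrinks as n
grows, which is the substance of the ρ = 0 limit.

## Pipeline

`run_integration_analysis` executes, per structure × stage cell: validation
→ GPA → PCA → all six pairwise group permutation tests → deviance against
the reference group → optional derived measures; per stage it adds the
brain–skull deviance correlation and the two-block PLS (pooled + per
group); plus Mann–Whitney/BH screening of scalar traits (the BH family is
all trait × stage × pair tests, mirroring the volume-test correction; shape
permutation tests are reported unadjusted) and logrank milestone tests.
Stages are analyzed cross-sectionally — separate GPA/PCA/PLS per stage, no
longitudinal registration — because the animals present at each stage may
differ.  Cell-level failures are isolated and logged without aborting the
run.  Every random operation derives its seed from the global seed and the
cell identity (CRC-32, kept below 2³¹), all CSV output uses a fixed float
format, and the manifest records the config hash, so a rerun with the same
config is bit-identical.

Mice lacking one modality are kept for single-structure analyses and
excluded pairwise from deviance correlations and PLS, which therefore
report their own (smaller) n.

`dose_rate` converts a drinking-water exposure to mg/kg/day
(concentration × intake / body mass), reporting the raw value and the
value rounded to the nearest 10 for summary use.

## Problem sizes used in validation

The shipped validation runs use: 2000 simulated null cohorts (n = 10 + 10,
199 permutations) for type-I calibration; 100 replicates × 5 strengths
(n = 25 pairs) for integration recovery; 100 random triangle pairs against
a 1e-4-rad rotation-grid oracle; 500 independent-block datasets for PLS
type-I; 50 random milestone datasets against an independent survival
implementation.  These sizes give Monte-Carlo standard errors comfortably
below the asserted margins while keeping a full validation run in the
low tens of seconds.
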