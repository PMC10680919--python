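# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Rating preprocessing

Raw ratings are 0–100 slider streams sampled every 0.5 s; one button press
moves the slider by 12 points. Streams are down-sampled to the fMRI TR
(2 s) by averaging the four samples in each TR window (a last-sample mode
is available; averaging is the default because it is robust to slider
jitter). Targets are range-normalized per trial; observers across all of
their trials pooled over modalities, so a single trial's maximum need not
reach 1. Constant streams cannot be normalized and are excluded with a
warning rather than imputed.

Normalized ratings are rescaled to 0–100 and folded into five
valence-independent intensity levels using the printed bin table: 41–60 →
1, 31–40 & 61–70 → 2, 21–30 & 71–80 → 3, 11–20 & 81–90 → 4, 0–10 & 91–100 →
5. The integer table is extended to the reals as closed/half-open intervals
with every boundary assigned to the less extreme level ([41, 60] → 1,
[31, 41) ∪ (60, 70] → 2, …). Note the table's center of symmetry is 50.5,
not 50: the map is invariant under v → 101 − v, and the test suite asserts
exactly that reflection.

Empathic accuracy per TR is `d = observer − target` on the normalized
scale; `|d|` is cut into five equal-width bins of [0, 1] with `|d| ≤ 0.2 →
level 5` (most accurate) and `|d| > 0.8 → level 1`. The signed `d` is
retained alongside the level because the measure is directional even though
the binning is not; only `|d|` feeds the level.

## Single-trial GLM

Per-(trial, level) boxcar regressors on the TR grid are convolved with a
canonical double-gamma HRF — positive lobe peaking at 6 s (gamma shape 7,
scale 1), undershoot peaking at 16 s (shape 17) with ratio 1/6, 32 s
support, peak-normalized. The design is [interest | 36 nuisance |
intercept]; fitting is plain per-voxel OLS (no prewhitening or high-pass
filter — nuisance regressors are the only confound model). Trial regressors
are QC'd by variance inflation factors computed against the full design; a
trial is dropped when its VIF exceeds the mean + 3 SD of the *other*
trials' VIFs (leave-one-out, so one extreme outlier cannot inflate its own
threshold; with all-equal VIFs nothing is dropped). Retained trial betas
are averaged into one map per intensity level; subjects left with fewer
than two levels are excluded downstream.

## LASSO-PCR signatures

Training maps are column-centered (no variance scaling — standard for
voxel features); an SVD supplies principal components, of which at most
`lasso_num = 120` (and never more than n − 1) enter an L1-penalized
regression on the component scores. The penalty is selected by
mean-squared error along scikit-learn's default regularization path under
5-fold internal cross-validation; internal folds are grouped by subject,
since shuffled folds let a subject's own maps inform the penalty for their
data and made the selection unstable in practice (occasionally collapsing
to the all-zero model). Component coefficients are back-projected to voxel
space, and the intercept is fixed so the mean training map maps to the mean
training outcome. A signature with all-zero weights is a legitimate outcome
when the internal CV finds no predictive component.

Evaluation is leave-one-subject-out: each subject's five maps are scored by
a signature trained without them, and the metric is that subject's Pearson
correlation between predicted and actual levels (constant predictions score
0). Permutation tests shuffle levels within subject — respecting the
grouped design — and use the add-one estimator
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`. Bootstrap inference resamples
subjects with replacement (maps move jointly; resamples with fewer than two
distinct subjects are redrawn), refits the full model, and thresholds
per-voxel `z = mean/SD` by Benjamini–Hochberg FDR; voxels never selected
across resamples have SD 0 and are assigned z = 0, p = 1.

## Separability and alignment

Condition separability uses a hinge-loss linear SVM with C = 1 under
leave-one-subject-out CV (both of a subject's maps held out together, so
subject identity cannot leak). Accuracy is tested two-sided against chance
by a binomial test; its SE is the binomial SE at the observed accuracy. ROC
curves pool decision values across folds; ties take midpoint steps, so the
trapezoid AUC equals the normalized Mann–Whitney U.

Alignment applies both signatures (dot product + intercept) to each
subject's low/high-accuracy maps and correlates the two expressions across
subjects within each tier. The default tier comparison is the
independent-samples Fisher z-test,
`z = (atanh r_high − atanh r_low) / sqrt(1/(n_l−3) + 1/(n_h−3))`;
a Steiger-type dependent-correlations variant using the Pearson–Filon
covariance of the cross-tier expressions is available by config (it reduces
to the Fisher test when the tiers are independent). Validation correlations
exclude the intercept (a constant leaves r unchanged); alignment
expressions include it.

The exploratory divergence regression predicts each voxel's low-accuracy
value from the inference expression with the ground-truth expression as
covariate, thresholds the predictor's t-map by BH-FDR (q = 0.05) and prunes
clusters below k = 25 voxels under 6-connectivity. It refuses collinear
expressions (|r| > 0.999).

## Synthetic-data generator

The generator emulates the study's structure, not its content:

- **Rating streams.** A "lazy caterpillar" walk: the slider move direction
  persists with probability 0.8 per 0.5 s sample, steps are ±12 points,
  moves beyond [0, 100] are dropped. Observers track an accuracy-weighted,
  lagged copy of the target blended with an independent walk plus smoothed
  noise, re-quantized to the slider grid.
- **Brain maps.** Two unit-norm voxel patterns with cosine similarity 0.29
  (the dissociation reported between the two signatures). A subject's map
  at level L in the ground-truth condition is
  `L·effect_gt·pattern_gt + mixing·L·effect_inf·pattern_inf +
  subject_offset + noise` (roles swapped for inference). Defaults:
  effects 1.0/level, mixing 0.3, subject-offset SD 1.0/voxel, noise SD
  1.1/voxel. The noise SD is calibrated so the full pipeline's LOO-CV mean
  r at study scale (100 subjects × 2000 voxels) lands at ≈ 0.53, the
  reported operating point; validation-condition signal is scaled by 0.6,
  reflecting the weaker unimodal validation correlations.
- **Accuracy-tier maps.** Generated directly at two tiers rather than via a
  trial-level simulation. Pattern coefficients are bivariate normal
  (mean 3, SD 3) with correlation −0.3 (low accuracy) and 0.35 (high).
  Because the patterns themselves overlap (cosine 0.29), the *expression*
  correlations sit above the coefficient concordances — approximately 0.3
  and 0.65 for well-estimated signatures at n = 100, near the reported
  alignment correlations.
- **GLM inputs.** 36 nuisance regressors (smoothed standardized noise plus
  one-hot spike columns) and voxel×time data `Y = XB + E` whose
  level-regressor coefficient rows follow the pattern/effect structure.
- **Geometry.** 2000 voxels as a 10×10×20 box inside a 12×12×22 volume
  (exercising NIfTI I/O without real-brain geometry); other voxel counts
  use a flat strip mask.

## Problem sizes

The generator's defaults are the study conditions (100 subjects, 5 levels,
2000 voxels). Tests and the demo pipeline run at 20 subjects; because a
rank-1 signal spike in iid noise becomes undetectable by PCA when the
voxel-to-sample ratio grows (the spike falls below the
Baik–Ben Arous–Péché threshold), desk-scale fixtures keep the study's
detectability regime by scaling voxels with subjects (typically 300–500
voxels for 20 subjects; the demo uses 500). One regression test runs the
20-subject × 2000-voxel configuration against a frozen reference value.
Bootstrap tests use 100–200 resamples; permutation calibration uses 39
permutations × 50 replicates.

## What passing tests do and do not show

The generator's noise is iid Gaussian per voxel: no spatial autocorrelation,
no physiological noise structure, no registration error, no
hemodynamic nonlinearity, and the latent signal is exactly rank-2 and
exactly linear in level. Passing recovery and calibration tests therefore
demonstrates that the *pipeline* is correct and statistically calibrated
under its own assumptions — not that real fMRI data carry the planted
structure. Conversely, effect sizes at desk scale (20 subjects) are noisy:
per-tier alignment correlations at n = 20 have sampling SD ≈ 0.2, so
demo-scale alignment z-values fluctuate in sign; the alignment-recovery
test uses 100-subject cohorts.

## Known limitations

- "lasso number = 120" is read as the maximum number of principal
  components entering the LASSO step; alternative toolbox conventions
  (e.g. a target count of active predictors) are not implemented.
- The prediction–outcome metric is plain within-subject Pearson r between
  predicted and actual levels, labeled as such.
- The SVM solver is a standard hinge-loss dual solver; only the decision
  boundary, not the optimizer, is treated as scientifically meaningful.
- Cluster pruning uses 6-connectivity in voxel space.
- No high-pass filtering, prewhitening, or AR noise modeling in the GLM.
- NIfTI geometry must match exactly; the package never resamples.
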