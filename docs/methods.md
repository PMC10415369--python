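# Methods

This note documents the models, numerical conventions and design choices
behind `gmdclassify`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Feature extraction

Grey-matter-density (GMD) volumes are voxel values in [0, 1] from modulated,
smoothed grey-matter segmentations. The package consumes such volumes as-is;
segmentation, nonlinear registration and modulation are upstream and out of
scope. Two conventions are pinned down because they silently change results
between implementations:

* **Mask rule.** A voxel enters the grey-matter mask iff grey-matter tissue
  probability > 0.40 AND white-matter probability < 0.60, both *strict*.
  Boundary voxels (exactly 0.40 / 0.60) are excluded. The mask is built once
  from a template tissue-probability pair, not per subject, and is serialized
  as a uint8 NIfTI for reproducibility.
* **Voxel linearization.** Feature-matrix columns follow ascending flat
  C-order index of the mask's true voxels; the rule is recorded in the mask
  file's header description so matrices from different runs are comparable.

Gaussian smoothing (`smooth_volume`) uses σ = FWHM/(2√(2 ln 2)) per axis in
voxel units, with reflective boundaries (constants are preserved; interior
responses equal plain convolution). It exists for synthetic volumes and for
completeness — real inputs arrive already smoothed at 8 mm FWHM.

## Classification engine

Per iteration, each psychosis group g ∈ {B1,B2,B3} (or {SZ,SAD,BD}) gets a
binary model g-vs-CON trained on 88 randomly drawn cases per class, the CON
draw shared across the three models of that iteration; every remaining
subject of every group is a test case. Sampling is without replacement and
ignores the other labeling scheme.

* **Model.** L2-regularized logistic regression minimizing
  `C·Σ log(1+exp(−y(w·x+b))) + ‖w‖²/2` with C = 1, the intercept
  unpenalized, solved by scikit-learn's deterministic L-BFGS path at
  tolerance 1e-6. No feature standardization or selection precedes the fit:
  GMD values share a common [0, 1] scale and the full in-mask voxel set is
  used. A unit test verifies the fitted weights against an independent
  generic minimizer of the same objective to 1e-4.
* **Evidence.** A subject's evidence is the predicted probability of the
  psychosis class, `expit(w·x+b)`. The decision threshold is 0.5; evidence
  exactly at the threshold is deliberately labelled CON so that ties resolve
  deterministically.
* **Metrics.** Balanced accuracy = (sensitivity + specificity)/2, robust to
  the unequal test-group sizes; the pooled (case-weighted) accuracy is also
  recorded since "overall accuracy" can be read either way. The interval
  test uses the balanced variant.
* **Intervals.** Equal-tail empirical percentile intervals with linear
  interpolation at level 99.17% (a Bonferroni-style guard for three models
  per scheme); "above chance" means the interval's lower bound exceeds 0.50.
  With n iterations the tail quantiles are order statistics near the
  extremes, so small n yields conservative (wide) intervals.
* **Specificity.** A model is specific iff its own-group accuracy is above
  chance and neither out-group transfer rate (fraction of the other groups'
  test cases labelled psychosis) is. The same percentile interval and chance
  reference are applied to transfer rates as to accuracies.
* **Reproducibility.** Every random draw flows from a master seed through a
  documented counter scheme (`default_rng([master_seed, 3, iteration])` for
  split draws; the generator uses analogous per-subject streams), so any
  iteration can be reproduced in isolation and full runs are bit-identical.

## Weight maps

For each model the per-iteration weight vectors are reduced to a voxel-wise
mean and a sign consistency (fraction of iterations whose weight sign matches
the mean's). This aggregation is a deliberate reconstruction chosen because
both summaries are computable from stored models and together express how
diffusely and how reliably a model uses each voxel; it applies no statistical
threshold, and individual voxels must not be over-interpreted — a feature's
contribution depends on every other feature in the model. Cross-model
comparisons of "strong, consistent" voxel counts use one pooled magnitude
cutoff (95th percentile of |mean weight| pooled over models); a per-model
cutoff would equalize the counts by construction.

## Evidence–behaviour regressions

Per iteration and outcome, an OLS regression on the full test sample uses
seven predictors besides the intercept: mean-centered B1-model evidence,
three group dummies against the CON reference, and the three
evidence-by-group interactions. Centering happens after listwise deletion of
missing outcome values, so it uses the analysis-sample mean; it reduces
collinearity between the main effect and the interactions and leaves all
non-intercept coefficients invariant to constant shifts of evidence.
Coefficients are pooled across iterations; significance is "the 95%
percentile interval excludes 0". Outcomes are analyzed on their raw scale by
default (a z-scoring flag exists) and missingness is handled by listwise
deletion only — no imputation. Note the interval treats iterations as
exchangeable draws although test samples overlap heavily across iterations;
it characterizes the stability of the coefficient under resampling of the
training data, not an independent-sample standard error. Multi-measure
panels are reduced by PCA of the correlation matrix (inputs z-scored,
components ordered by eigenvalue, each component's sign fixed so its
largest-|loading| measure loads positively, rows with missing values
excluded before fitting).

## Synthetic cohorts

The generator produces, per subject, `clip(baseline − deficit_g(v) +
offset_i + ε_iv, 0, 1)` on a small voxel grid, with Gaussian subject offsets
(`subject_sd`, default 0.01), Gaussian voxel noise (`voxel_sd`, default
0.12) and baseline 0.5 — clipping thus sits ~4σ out and its bias is
negligible. Group deficits combine a *shared* psychosis pattern (scaled per
group) and *group-specific* patterns on disjoint spherical supports inside a
smooth grey-matter bump; the template tissue volumes are constructed so the
mask rule both includes an interior shell and excludes the exterior and a
white-matter core. Default group sizes are 150/185/222/251 (B1/B2/B3/CON)
with diagnosis labels (242/138/177 SZ/SAD/BD) assigned independently of
biotype, mirroring the reference cohort's sizes.

Clinical outcomes are linear in each subject's **B1-pattern expression** —
the z-scored mean GMD shortfall over the union of the shared and B1-specific
supports — plus group offsets and noise, with the slope identical across
groups (group-invariant by construction) and missingness completely at
random. The expression score is the generator's explicit latent standing in
for what classifier evidence tracks; defining it as a support mean makes
slope recovery analytically checkable. The default reading-score-like
outcome uses slope −5 per expression SD and noise SD 14, in line with the
reference cohort's score dispersion.

### Preset calibration and what the tests show

The `paper_like` magnitudes (shared 0.045; specific 0.036/0.012/0.011 for
B1/B2/B3; B3 expresses the shared pattern at scale 0.4) were calibrated once
to reproduce the *qualitative* headline structure and then frozen:

* accuracy gradient B1 > B2 > B3;
* only the B1 model specific: its discriminant is dominated by the
  B1-specific pattern, so B2/B3 transfer stays below chance, while the B2
  model is dominated by the shared pattern and therefore labels B1 cases
  psychosis above chance.

At desk scale the out-group test sets are small (e.g. 62 B1 test cases), so
iteration-to-iteration transfer rates carry binomial noise of ~0.06 SD; for
the interval verdicts to be stable, the calibrated effect sizes are larger
than real-data effects and the resulting accuracies (≈0.94/0.81/0.58) sit
above the moderate values typical of real GMD classifiers. The synthetic
experiments therefore validate the *machinery and its inferential logic*
(chance calibration, interval behaviour, specificity verdicts, group
invariance recovery), not real-data effect sizes. The generator also omits
scanner/site effects, registration error and anatomical structure, so
passing tests say nothing about preprocessing robustness.

The subject-offset SD deserves a note: a large global offset is a rank-one
noise direction that a high-dimensional linear model cancels using
out-of-support voxels, which would decouple evidence from the expression
latent within groups. The default keeps the offset small so that
within-group expression variance is carried by support-level voxel noise,
which evidence does track — this is what makes the group-invariant outcome
link recoverable as a significant evidence main effect. A related
nonlinearity is worth knowing about: because evidence is a logistic of the
linear score, groups near the probability extremes have compressed evidence
variance, which biases interaction coefficients slightly positive even under
a group-invariant link; with the default noise levels this bias stays well
inside the interactions' 95% intervals.

## Problem sizes

Tests and the acceptance script run the full 808-subject design on reduced
grids — 24³ (≈1900 mask voxels) for the effect-recovery suites, 40³
(≈9300 mask voxels) for the chance-calibration run — with 150–200
iterations, chosen so the whole suite completes in a few minutes while the
interval machinery still has resolution at the 99.17% level. Under a null
cohort the mean balanced accuracy over 200 iterations deviates from 50% by
up to ~2–3 percentage points for a single model because iterations share
test subjects and a finite cohort's chance alignments do not average out;
averaging the three models' means reduces this, and the calibration test
asserts the three-model average within ±1.5 points.
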