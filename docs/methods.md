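# Methods

## Model and assumptions

The pipeline treats each subject as a point in voxel space: a spatially
normalized, smoothed, nonmodulated gray-matter map flattened over a mask.
The decoding model is deliberately simple and linear throughout — PCA for
dimensionality reduction, a univariate Fisher score for ordering the
resulting coefficients, and a linear soft-margin SVM for classification —
so that the final decision function is a single hyperplane in voxel space
and can be mapped back onto the brain.

Assumptions this inherits:

- all volumes share one grid and voxel size (spatial normalization happened
  upstream; the package validates geometry but does not register images);
- class structure is linearly separable *in the PCA subspace of the
  training set*, or at least approachable by a soft margin;
- the Fisher ranking treats coefficients one at a time; interactions between
  coefficients are captured only by the multivariate SVM that follows;
- with n subjects, the centered data span at most n − 1 dimensions, so the
  feature extraction can never yield more than n − 1 coefficients.

## Synthetic cohorts: what they emulate, and what they do not

`synthetic.generate_cohort` draws cohorts of `template + (effect) + noise`:

- **template** — a unit-intensity ellipsoid (semi-axes 40% of the grid)
  softened by a Gaussian kernel; a stand-in for a smoothed mean gray-matter
  probability map. A `flat` template is available for analytic tests.
- **effect** — a union of spherical blobs convolved with the same kernel and
  rescaled so its peak equals `effect_magnitude`, added to every group B
  (+1, "patient") volume. The *unsmoothed* sphere union is returned as the
  ground-truth mask, so mask membership is crisp while the planted signal is
  smooth, like real volumetric group differences.
- **noise** — i.i.d. Gaussian per voxel and subject. Subject smoothing (a
  preprocessing step, applied after generation) correlates it spatially,
  exactly as scanner/segmentation noise is correlated after a VBM pipeline.

Defaults are the package's study conditions and were fixed before any
evaluation: 17 + 17 subjects; 32 × 32 × 32 grid at 4 mm voxels (a head-sized
field of view at desk scale; the production geometry 121 × 145 × 121 at
1.5 mm is available by config); `noise_sd = 0.1` against a unit template
(≈10% intensity noise); `effect_magnitude = 0.2`, i.e. twice the noise SD —
the stated strong-effect condition; two bilateral spherical regions of
radius 5 voxels (multifocal, as real group differences tend to be; their
total size, ~1000 voxels, was chosen to be commensurate with a top-5% voxel
set of the default grid so that overlap scores are meaningful); softening
FWHM 8 mm, matching the preprocessing kernel.

Not emulated: MRI physics, bias fields, motion, anatomy beyond an ellipsoid,
inter-subject anatomical variability beyond additive noise, or diagnostic
subtypes. Passing tests therefore demonstrate the *pipeline's* correctness
and calibration, not expected performance on clinical data.

## Numerical conventions

- **Smoothing**: separable Gaussian, per-axis σ = FWHM / (voxel · 2√(2 ln 2)),
  reflect boundary. Reflection folds every kernel tail back into the grid,
  so total intensity is conserved (checked to 1e-6 relative) and edge voxels
  are not attenuated on small test grids.
- **PCA**: thin SVD of the centered n × p matrix (never the p × p
  covariance). Eigenvalue cutoff λ / λ_max > 1e-10 defines "nonzero";
  eigenvalues use the n − 1 denominator so training-coefficient variances
  equal them exactly. Component signs are fixed (largest-magnitude entry
  positive) purely for reproducibility.
- **Fisher ranking**: descending score, ties broken by ascending component
  index; zero pooled variance with distinct means scores +inf (ranked
  first), with equal means scores 0.
- **SVM**: scikit-learn's SVC with a linear kernel and KKT tolerance 1e-10,
  tight enough that mirrored problems (label swap, component sign flips)
  produce mirrored solutions to ~1e-8. C defaults to 1 and is exposed.
  Decision values are recomputed from the stored dual weights; y(x) = 0
  predicts +1.
- **Stratified partition**: per class, a seeded shuffle followed by a
  round-robin deal whose pointer continues across classes — per-class subset
  sizes differ by at most one and no subset is empty even with more subsets
  than members of a class (34 subjects in 20 subsets is a valid plan).
- **Metrics**: pooled over folds, never averaged per fold. Specificity and
  sensitivity default to same-group denominators ("standard"); the
  "as-printed" convention with mixed-group denominators is provided because
  both readings of the defining formulas exist. Zero denominators yield NaN.
- **Folds short of k**: a fold whose training set yields fewer than the
  requested k components uses all it has and the event is recorded in the
  result, so curves can extend to the largest k any fold supports.
- **Maps**: back-projection for maps omits the training mean (the mean
  carries no class information). The activation pattern uses
  aⱼ = λⱼ wⱼ / var(ŷ) with var(ŷ) over the training set at ddof = 1,
  matching the eigenvalue convention, which makes the diagonal shortcut
  exactly equal to the dense cov(X)·w / var(ŷ) definition. Map
  normalization defaults to magnitudes ("abs-minmax"); signed normalization
  is available. Final maps come from a model trained on the full cohort at
  the primary scheme's best k; per-fold maps can be built through the
  library API.

## Design choices that were genuinely open

- **Per-fold vs. global feature extraction.** Fitting PCA separately on a
  test set would destroy feature correspondence between train and test;
  the pipeline always fits on the training fold and projects the test fold.
- **Null-calibration readout.** The chance-level check on effect-free
  cohorts reads the accuracy at the *full* component count, a single
  pre-specified point of the curve; taking the best accuracy over ~30 values
  of k is upward-biased by selection and would not test calibration.
- **Generator/preprocessing separation.** Noise is added to the unsmoothed
  subject volume and smoothing is a preprocessing responsibility, so the
  generator stays a pure sampling model and the same cohort can be analyzed
  at any FWHM.
- **Uncompressed NIfTI by default.** gzip embeds modification times in its
  headers; plain `.nii` keeps repeated runs byte-identical, which the
  pipeline guarantees end to end (same config + seeds ⇒ identical CSV, JSON
  and NIfTI payloads).

## Problem sizes

Unit and end-to-end tests run on 16³–32³ grids with cohorts of 16–34
subjects; the full-size 121 × 145 × 121 geometry is exercised for I/O and
supported throughout by the same code paths (the PCA works in sample space,
so memory scales with n × p, about 0.5 GB at production geometry for 34
subjects).

## Known limitations

- No hyperparameter search (C is fixed by config); no nested CV.
- No permutation-test p-values for accuracies or map voxels; the null
  calibration of the pipeline is established on simulated null cohorts
  instead.
- The "as-printed" metric convention can exceed sensible bounds on heavily
  imbalanced confusion tables precisely because its denominators mix groups;
  it is provided for comparability, not recommended.
- Linear kernel only, by design: nonlinear kernels admit no primal weight
  vector and hence no voxel maps.
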