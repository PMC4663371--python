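# vbmdecode

Individual-level classification of structural brain volumes, for researchers
who want to ask "can this subject's gray-matter map tell us which group they
belong to, and which voxels carry that information?" rather than only "do the
group means differ?". The package implements a complete multivoxel
pattern-analysis pipeline for spatially normalized, smoothed gray-matter
maps (e.g. VBM output), together with a synthetic cohort generator with
known ground truth so that every stage can be validated without access to
clinical data.

## The method

Given n subjects with p voxels each (p ≫ n) and binary labels t ∈ {±1}:

1. **Smoothing & vectorization.** Each volume is smoothed with a Gaussian
   kernel of stated FWHM (default 8 mm) and flattened over a brain mask into
   a row of the n × p feature matrix X.
2. **PCA.** The centered X is decomposed by thin SVD; at most n − 1
   components carry nonzero eigenvalue. Subject i's features become its
   *PCA coefficients* — the projection of its centered voxel vector onto the
   components. Eigenvalues are the sample variances (n − 1 denominator) of
   the training coefficients.
3. **Fisher ranking.** Each coefficient j is scored by the Fisher
   Discriminant Ratio FDR_j = (μ₁ − μ₂)² / (σ₁² + σ₂²) from its class means
   and variances, and the coefficients are reordered by descending FDR.
4. **Linear SVM.** The first k ranked coefficients feed a soft-margin linear
   SVM with decision function y(x) = Σₙ aₙ tₙ ⟨x, xₙ⟩ + b.
5. **Stratified k-fold CV.** Steps 2–4 are refitted inside each training
   fold (no leakage); pooled test predictions give
   Accuracy = N_CC / N, Specificity and Sensitivity as functions of k,
   for 20-fold and 10-fold schemes.
6. **Discriminative maps.** A final model is back-projected to voxel space:
   the *weight map* Σₙ aₙ tₙ (back-projected xₙ), and the *activation
   pattern* a = cov(X)·w / var(ŷ), which for uncorrelated PCA coefficients
   reduces to aⱼ = λⱼ wⱼ / var(ŷ). Maps are normalized to [0, 1] and can be
   thresholded (e.g. at 50%).

## Worked example

```bash
python examples/02_cross_validation.py
```

prints (strong-effect synthetic cohort, 17 controls + 17 patients, planted
effect twice the noise SD):

```
20-fold CV: best k=1 of 32 -> accuracy 1.00, specificity 1.00, sensitivity 1.00
...
10-fold CV: best k=1 of 30 -> accuracy 1.00, specificity 1.00, sensitivity 1.00
```

i.e. with a planted effect well above the (smoothed) noise floor the
classifier separates the groups perfectly from the first Fisher-ranked
coefficient onward; on a null cohort (`effect_magnitude=0`) the same curves
hover around 0.5. `examples/03_discriminative_maps.py` then shows that the
top-5% voxels of the activation map recover the planted effect regions with
Dice ≈ 0.77, and `examples/01_simulate_cohort.py` documents what the
generator plants.

The same pipeline runs from the shell:

```bash
vbmdecode simulate --out cohort/ --seed 0
vbmdecode run --config config.yaml
vbmdecode report run_dir/
```

## Layout

- `src/vbmdecode/` — `synthetic` (cohort generator), `preprocess`
  (smoothing/masking/vectorization), `pca` (PCA + Fisher ranking), `svm`
  (linear SVM), `crossval` (stratified CV + metrics), `maps` (weight /
  activation / normalized / thresholded maps), `pipeline` + `cli`
  (end-to-end runner).
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  conventions and limitations.
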