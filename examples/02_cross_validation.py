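"""Cross-validated decoding accuracy as a function of retained components.

Runs the full chain — smoothing, PCA, Fisher-ratio ranking, linear SVM —
under 20-fold and 10-fold stratified CV on a strong-effect synthetic cohort
and prints the pooled accuracy / specificity / sensitivity curves' best
points.  Sensitivity refers to the patient (+1) group.
"""

import vbmdecode as vd

cohort = vd.generate_cohort(vd.CohortConfig(seed=1))
smoothed = [vd.gaussian_smooth(v, 8.0) for v in cohort.volumes]
features = vd.vectorize(smoothed, vd.build_mask(smoothed))

for scheme in (20, 10):
    result = vd.run_cv(features, cohort.labels, n_subsets=scheme, C=1.0, seed=1)
    acc, spec, sens = result.best_metrics
    print(f"{scheme}-fold CV: best k={result.best_k} of {result.k_max} "
          f"-> accuracy {acc:.2f}, specificity {spec:.2f}, sensitivity {sens:.2f}")
    head = result.per_k.head(5).to_string(index=False, float_format=lambda v: f"{v:.2f}")
    print("first rows of the metric curve:")
    print(head)
# With a planted effect of twice the noise SD the classifier separates the
# groups almost perfectly even with few components; on a null cohort
# (effect_magnitude=0) the same curves hover around 0.5.
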