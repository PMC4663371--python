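"""Voxel-wise discriminative maps and their overlap with the planted effect.

Trains a linear SVM on the top Fisher-ranked PCA coefficients of the full
cohort, builds the SVM weight map and the covariance-corrected activation
map, normalizes and thresholds the latter at 50%, and measures how well the
top-5% activation voxels recover the ground-truth effect regions (Dice).
"""

import numpy as np

import vbmdecode as vd

cohort = vd.generate_cohort(vd.CohortConfig(seed=42))
smoothed = [vd.gaussian_smooth(v, 8.0) for v in cohort.volumes]
features = vd.vectorize(smoothed, vd.build_mask(smoothed))

model = vd.fit_pca(features)
coeffs = vd.project(model, features)
ranking = vd.fdr_rank(coeffs, cohort.labels)
top = ranking.order[:20]
clf = vd.train(coeffs.values[:, top], cohort.labels, C=1.0)

wmap = vd.weight_map(clf, model, features, component_subset=top)
inputs = vd.build_pattern_inputs(clf, model, coeffs.values[:, top], component_subset=top)
amap = vd.haufe_activation_map(inputs, features)
norm = vd.normalize_map(amap)            # |v| rescaled onto [0, 1]
thresh = vd.threshold_map(norm, 0.5)     # keep voxels >= 50% of the maximum

mag = np.abs(amap.data)
top5 = mag >= np.quantile(mag, 0.95)
dice = vd.dice_overlap(top5, cohort.effect_mask)

print(f"PCA kept {model.n_components} components; SVM trained on the top {len(top)} by Fisher ratio")
print(f"weight map peak voxel:     {tuple(map(int, np.unravel_index(np.abs(wmap.data).argmax(), wmap.data.shape)))}")
print(f"activation map peak voxel: {tuple(map(int, np.unravel_index(mag.argmax(), mag.shape)))}")
print(f"voxels surviving the 50% threshold: {thresh.meta['surviving_voxels']}")
print(f"Dice(top-5% |activation|, planted mask) = {dice:.2f}")
# A Dice well above chance means the corrected map points at the voxels
# where the group difference was actually planted, not merely at voxels the
# decoder happened to weight.
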