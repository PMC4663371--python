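"""Discriminative maps: route identity, covariance correction, normalization."""

import numpy as np
import pytest

import vbmdecode as vd
from vbmdecode.errors import DegenerateInputError

from conftest import cohort_features, small_config


def fit_chain(features, labels, k, C=1.0):
    model = vd.fit_pca(features)
    coeffs = vd.project(model, features)
    top = vd.fdr_rank(coeffs, labels).order[: min(k, model.n_components)]
    clf = vd.train(coeffs.values[:, top], labels, C=C)
    return model, coeffs, top, clf


@pytest.fixture(scope="module")
def fitted(strong_features, strong_cohort):
    return fit_chain(strong_features, strong_cohort.labels, k=15)


class TestWeightMap:
    def test_zero_dual_weights_give_zero_map(self, fitted, strong_features):
        model, _, top, clf = fitted
        silent = vd.LinearSVMModel(
            dual_weights=np.zeros_like(clf.dual_weights),
            support_labels=clf.support_labels,
            support_samples=clf.support_samples,
            bias=0.0,
            C=clf.C,
        )
        vmap = vd.weight_map(silent, model, strong_features, component_subset=top)
        np.testing.assert_array_equal(vmap.data, 0.0)

    def test_sample_sum_equals_primal_back_projection(self, fitted, strong_features):
        model, _, top, clf = fitted
        by_samples = vd.weight_map(clf, model, strong_features, component_subset=top, route="samples")
        by_primal = vd.weight_map(clf, model, strong_features, component_subset=top, route="primal")
        scale = np.abs(by_primal.data).max()
        assert np.abs(by_samples.data - by_primal.data).max() < 1e-8 * scale

    def test_label_flip_negates_map(self, strong_features, strong_cohort):
        model, coeffs, top, clf = fit_chain(strong_features, strong_cohort.labels, k=10)
        clf_neg = vd.train(coeffs.values[:, top], -strong_cohort.labels, C=1.0)
        m1 = vd.weight_map(clf, model, strong_features, component_subset=top)
        m2 = vd.weight_map(clf_neg, model, strong_features, component_subset=top)
        np.testing.assert_allclose(m1.data, -m2.data, atol=1e-8 * np.abs(m1.data).max())

    def test_component_sign_flip_leaves_magnitude_map_unchanged(self, strong_features, strong_cohort):
        labels = strong_cohort.labels
        model, coeffs, top, clf = fit_chain(strong_features, labels, k=8)
        flipped_model = vd.PCAModel(
            mean_vector=model.mean_vector,
            components=model.components * np.where(np.arange(model.n_components) == top[0], -1.0, 1.0)[:, None],
            eigenvalues=model.eigenvalues,
            n_training_samples=model.n_training_samples,
        )
        flipped_coeffs = vd.project(flipped_model, strong_features)
        clf_f = vd.train(flipped_coeffs.values[:, top], labels, C=1.0)
        m1 = vd.weight_map(clf, model, strong_features, component_subset=top)
        m2 = vd.weight_map(clf_f, flipped_model, strong_features, component_subset=top)
        np.testing.assert_allclose(np.abs(m1.data), np.abs(m2.data), atol=1e-7 * np.abs(m1.data).max())


class TestActivationMap:
    def test_whitened_coefficients_make_pattern_parallel_to_weights(self, rng):
        # equal eigenvalues -> identity covariance -> pattern ∝ weights
        n, k, p = 20, 3, 50
        comps = np.linalg.qr(rng.normal(size=(p, k)))[0].T
        model = vd.PCAModel(np.zeros(p), comps, np.ones(k), n)
        geometry = vd.FeatureMatrix(
            values=np.zeros((1, p)),
            mask=np.ones((5, 5, 2), dtype=bool),
            subject_ids=["s0"],
            voxel_size_mm=(1.0, 1.0, 1.0),
        )
        coeffs = rng.normal(size=(n, k))
        labels = np.array([-1, 1] * 10)
        clf = vd.train(coeffs, labels)
        inputs = vd.build_pattern_inputs(clf, model, coeffs)
        amap = vd.haufe_activation_map(inputs, geometry).data.ravel()
        wmap = vd.weight_map(clf, model, geometry).data.ravel()
        cos = amap @ wmap / (np.linalg.norm(amap) * np.linalg.norm(wmap))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_shortcut_equals_brute_force_covariance_oracle(self, strong_features, strong_cohort):
        # small instance: dense cov(X) @ w / var(ŷ) from the raw coefficients
        model, coeffs, top, clf = fit_chain(strong_features, strong_cohort.labels, k=3)
        train_coeffs = coeffs.values[:, top]
        inputs = vd.build_pattern_inputs(clf, model, train_coeffs, component_subset=top)
        shortcut = inputs.eigenvalues * clf.primal_weights / inputs.decision_variance
        yhat = train_coeffs @ clf.primal_weights + clf.bias
        brute = np.cov(train_coeffs, rowvar=False) @ clf.primal_weights / np.var(yhat, ddof=1)
        assert np.abs(shortcut - brute).max() < 1e-6

    def test_constant_classifier_rejected(self, rng):
        comps = np.eye(2, 10)
        model = vd.PCAModel(np.zeros(10), comps, np.array([2.0, 1.0]), 4)
        clf = vd.LinearSVMModel(
            dual_weights=np.zeros(2),
            support_labels=np.array([-1, 1]),
            support_samples=np.zeros((2, 2)),
            bias=0.5,
            C=1.0,
        )
        with pytest.raises(DegenerateInputError):
            vd.build_pattern_inputs(clf, model, rng.normal(size=(4, 2)) * 0 + 1.0)

    def test_peak_localizes_inside_planted_effect(self):
        # effect much stronger than noise; peak voxel inside the mask in >= 8/10 seeds
        hits = 0
        for s in range(10):
            cohort = vd.generate_cohort(small_config(effect_magnitude=0.5, noise_sd=0.1, seed=400 + s))
            fm = cohort_features(cohort)
            model, coeffs, top, clf = fit_chain(fm, cohort.labels, k=10)
            inputs = vd.build_pattern_inputs(clf, model, coeffs.values[:, top], component_subset=top)
            amap = vd.haufe_activation_map(inputs, fm)
            peak = np.unravel_index(np.abs(amap.data).argmax(), amap.data.shape)
            hits += bool(cohort.effect_mask[peak])
        assert hits >= 8


class TestNormalizeThreshold:
    def test_normalized_range_is_exactly_unit(self, fitted, strong_features):
        model, _, top, clf = fitted
        vmap = vd.weight_map(clf, model, strong_features, component_subset=top)
        norm = vd.normalize_map(vmap)
        assert norm.data.min() == 0.0
        assert norm.data.max() == 1.0

    def test_abs_minmax_hand_example(self):
        vmap = vd.VoxelMap(np.array([-4.0, 0.0, 2.0]).reshape(1, 1, 3), kind="weight")
        norm = vd.normalize_map(vmap, "abs-minmax")
        np.testing.assert_allclose(norm.data.ravel(), [1.0, 0.0, 0.5])

    def test_signed_minmax_idempotent_on_unit_range(self):
        data = np.array([0.0, 0.3, 1.0]).reshape(1, 1, 3)
        norm = vd.normalize_map(vd.VoxelMap(data, kind="weight"), "signed-minmax")
        np.testing.assert_allclose(norm.data, data)

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            vd.normalize_map(vd.VoxelMap(np.ones((2, 2, 2)), kind="weight"))

    def test_threshold_zero_keeps_everything(self):
        norm = vd.normalize_map(vd.VoxelMap(np.arange(8.0).reshape(2, 2, 2), kind="weight"), "signed-minmax")
        out = vd.threshold_map(norm, 0.0)
        np.testing.assert_array_equal(out.data, norm.data)

    def test_threshold_one_keeps_only_maximum(self):
        norm = vd.normalize_map(vd.VoxelMap(np.arange(8.0).reshape(2, 2, 2), kind="weight"), "signed-minmax")
        out = vd.threshold_map(norm, 1.0)
        assert out.meta["surviving_voxels"] == 1

    def test_half_threshold_count_by_definition(self):
        values = np.array([0.0, 0.25, 0.5, 0.75, 1.0]).reshape(1, 1, 5)
        out = vd.threshold_map(vd.VoxelMap(values, kind="normalized"), 0.5)
        assert out.meta["surviving_voxels"] == 3

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            vd.threshold_map(vd.VoxelMap(np.zeros((2, 2, 2)), kind="weight"), 0.5)


def test_dice_overlap_hand_values():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros((4, 4, 4), dtype=bool)
    a[:2] = True   # 32 voxels
    b[1:3] = True  # 32 voxels, 16 shared
    assert vd.dice_overlap(a, b) == pytest.approx(0.5)


def test_write_map_round_trip(tmp_path, fitted, strong_features):
    import nibabel as nib

    model, _, top, clf = fitted
    vmap = vd.weight_map(clf, model, strong_features, component_subset=top)
    path = vd.write_map(vmap, tmp_path / "w.nii", voxel_size_mm=strong_features.voxel_size_mm)
    loaded = np.asarray(nib.load(path).dataobj)
    np.testing.assert_allclose(loaded, vmap.data, atol=1e-6 * np.abs(vmap.data).max())
    assert (tmp_path / "w.json").exists()
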