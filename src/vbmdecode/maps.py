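"""Voxel-wise discriminative maps from a trained linear SVM.

Two maps are produced, both back-projected from PCA-coefficient space to the
voxel grid without the training mean (the mean carries no class
information):

* the **weight map** — each (mean-free, back-projected) training brain
  multiplied by its SVM dual weight a_n·t_n and summed voxelwise; this is
  algebraically identical to back-projecting the primal weight vector
  w = Σ a_n t_n x_n, and both routes are implemented;
* the **activation map** — the weight vector turned into a forward-model
  pattern by the covariance correction a = cov(X)·w / var(ŷ).  A decoder's
  weights alone are not interpretable as sources; the correction makes them
  so.  Because training PCA coefficients are uncorrelated with per-component
  variance equal to the eigenvalues, cov(X) is diagonal and the pattern
  reduces to a_j = λ_j · w_j / var(ŷ) componentwise, which is exact under
  this package's eigenvalue convention (both variances use denominator n−1).

Maps can be normalized to [0, 1] (by default on magnitudes, matching a
single-color-scale display) and thresholded at a fraction of the maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, ShapeMismatchError
from .pca import PCAModel, back_project
from .preprocess import FeatureMatrix
from .svm import LinearSVMModel, decision_value

__all__ = [
    "VoxelMap",
    "PatternMapInputs",
    "build_pattern_inputs",
    "weight_map",
    "haufe_activation_map",
    "normalize_map",
    "threshold_map",
    "write_map",
    "dice_overlap",
]

MAP_KINDS = ("weight", "activation", "normalized", "thresholded")


@dataclass
class VoxelMap:
    """A 3D per-voxel importance map plus provenance metadata."""

    data: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")
        self.data = np.asarray(self.data, dtype=float)


@dataclass
class PatternMapInputs:
    """Everything the covariance correction needs, in coefficient space."""

    primal_weights: np.ndarray  # w over the employed components
    eigenvalues: np.ndarray  # per-component training variances (diag of cov)
    decision_variance: float  # var(ŷ) over the training set, ddof=1
    pca_model: PCAModel
    component_subset: np.ndarray  # indices of employed components

    def __post_init__(self) -> None:
        if self.decision_variance <= 0:
            raise DegenerateInputError("var(ŷ) must be positive; the classifier is constant on the training set")


def build_pattern_inputs(
    model: LinearSVMModel,
    pca_model: PCAModel,
    training_coefficients: np.ndarray,
    component_subset=None,
) -> PatternMapInputs:
    """Assemble covariance-correction inputs from a trained fold/model.

    ``training_coefficients`` are the (n × k) coefficients the SVM was
    trained on, i.e. already restricted to ``component_subset`` (defaults to
    the first k components in original order).
    """
    coeffs = np.asarray(getattr(training_coefficients, "values", training_coefficients), dtype=float)
    if component_subset is None:
        component_subset = np.arange(coeffs.shape[1])
    component_subset = np.asarray(component_subset, dtype=int)
    if coeffs.shape[1] != component_subset.size:
        raise ShapeMismatchError(
            f"{coeffs.shape[1]} coefficient columns but {component_subset.size} components in subset"
        )
    yhat = np.asarray(decision_value(model, coeffs), dtype=float)
    var_yhat = float(yhat.var(ddof=1))
    if var_yhat <= 0:
        raise DegenerateInputError("var(ŷ) is zero: degenerate classifier")
    return PatternMapInputs(
        primal_weights=model.primal_weights,
        eigenvalues=pca_model.eigenvalues[component_subset],
        decision_variance=var_yhat,
        pca_model=pca_model,
        component_subset=component_subset,
    )


def _to_grid(vector: np.ndarray, geometry: FeatureMatrix) -> np.ndarray:
    return geometry.unflatten(vector)


def weight_map(
    model: LinearSVMModel,
    pca_model: PCAModel,
    geometry: FeatureMatrix,
    component_subset=None,
    route: str = "samples",
) -> VoxelMap:
    """SVM weight map on the voxel grid.

    ``route="samples"`` sums each support sample's mean-free back-projection
    scaled by its dual weight a_n·t_n; ``route="primal"`` back-projects the
    primal weight vector directly.  The two are the same linear combination
    of components and agree to numerical precision.
    """
    if component_subset is None:
        component_subset = np.arange(model.n_features)
    component_subset = np.asarray(component_subset, dtype=int)
    if component_subset.size != model.n_features:
        raise ShapeMismatchError(
            f"model has {model.n_features} coefficient dimensions but subset lists {component_subset.size}"
        )
    if route == "samples":
        signed = model.dual_weights * model.support_labels
        brains = back_project(pca_model, model.support_samples, component_subset, include_mean=False)
        vec = signed @ brains
    elif route == "primal":
        vec = back_project(pca_model, model.primal_weights, component_subset, include_mean=False)[0]
    else:
        raise ValueError(f"route must be 'samples' or 'primal', got {route!r}")
    return VoxelMap(
        data=_to_grid(vec, geometry),
        kind="weight",
        meta={"route": route, "components": component_subset.tolist(), "pca_model_id": pca_model.model_id},
    )


def haufe_activation_map(inputs: PatternMapInputs, geometry: FeatureMatrix) -> VoxelMap:
    """Forward-model activation pattern on the voxel grid.

    Componentwise a_j = λ_j · w_j / var(ŷ) (diagonal covariance of
    uncorrelated PCA coefficients), then mean-free back-projection.
    """
    pattern_coeffs = inputs.eigenvalues * inputs.primal_weights / inputs.decision_variance
    vec = back_project(inputs.pca_model, pattern_coeffs, inputs.component_subset, include_mean=False)[0]
    return VoxelMap(
        data=_to_grid(vec, geometry),
        kind="activation",
        meta={
            "components": inputs.component_subset.tolist(),
            "decision_variance": inputs.decision_variance,
            "pca_model_id": inputs.pca_model.model_id,
        },
    )


def normalize_map(vmap: VoxelMap, mode: str = "abs-minmax") -> VoxelMap:
    """Rescale a map onto [0, 1].

    "abs-minmax" (default) displays magnitudes: v ← (|v|−min|v|)/(max|v|−min|v|).
    "signed-minmax" maps the raw values affinely onto [0, 1].  A constant map
    has no range to normalize and is an error.
    """
    data = vmap.data
    if mode == "abs-minmax":
        data = np.abs(data)
    elif mode != "signed-minmax":
        raise ValueError(f"mode must be 'abs-minmax' or 'signed-minmax', got {mode!r}")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise DegenerateInputError("constant map cannot be normalized")
    return VoxelMap(
        data=(data - lo) / (hi - lo),
        kind="normalized",
        meta={**vmap.meta, "normalization": mode, "source_kind": vmap.kind},
    )


def threshold_map(vmap: VoxelMap, threshold: float) -> VoxelMap:
    """Zero out normalized-map voxels below ``threshold`` (a fraction in [0, 1])."""
    if vmap.kind != "normalized":
        raise ValueError(f"threshold_map expects a normalized map, got kind {vmap.kind!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    surviving = vmap.data >= threshold
    data = np.where(surviving, vmap.data, 0.0)
    return VoxelMap(
        data=data,
        kind="thresholded",
        meta={**vmap.meta, "threshold": threshold, "surviving_voxels": int(surviving.sum())},
    )


def dice_overlap(binary_a: np.ndarray, binary_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two binary grids."""
    a = np.asarray(binary_a, dtype=bool)
    b = np.asarray(binary_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise DegenerateInputError("both masks are empty")
    return 2.0 * (a & b).sum() / denom


def write_map(vmap: VoxelMap, path: str | Path, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a map as uncompressed NIfTI with a JSON sidecar of its metadata."""
    path = Path(path)
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(vmap.data.astype(np.float32), affine), path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"kind": vmap.kind, **vmap.meta}, indent=1, sort_keys=True))
    return path
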