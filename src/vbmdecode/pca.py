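"""PCA subspace learning, projection/back-projection, and Fisher-ratio ranking.

A cohort of n subjects with p voxels (p >> n) spans at most an (n−1)-dim
subspace after mean-centering, so the principal components are obtained from
a thin SVD of the centered matrix; this is mathematically identical to an
eigendecomposition of the p × p sample covariance but never forms it.

Conventions fixed here and relied on downstream:

* eigenvalues are the *sample variances* (denominator n−1) of the training
  coefficients, so ``var(project(model, X_train)[:, j]) == eigenvalues[j]``
  exactly — this makes the diagonal-covariance shortcut for activation
  patterns exact;
* components with eigenvalue below ``1e-10`` of the largest are treated as
  numerically zero and dropped, and at most n−1 components are ever kept;
* each component's sign is fixed so its largest-magnitude entry is positive
  (components are only defined up to sign; the choice is for reproducibility
  and has no downstream effect on accuracies or magnitude maps).

The Fisher Discriminant Ratio of a coefficient with class means μ1, μ2 and
class variances σ1², σ2² is ``(μ1 − μ2)² / (σ1² + σ2²)`` — a univariate
separability score used only to *order* the coefficients fed to the
classifier (distinct from the false-discovery rate).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ShapeMismatchError

__all__ = ["PCAModel", "CoefficientMatrix", "FeatureRanking", "fit_pca", "project", "back_project", "fdr_rank"]

EIGENVALUE_RTOL = 1e-10


def _as_matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


@dataclass
class PCAModel:
    """Learned subspace: mean, orthonormal component rows, eigenvalues."""

    mean_vector: np.ndarray  # (p,)
    components: np.ndarray  # (k, p), orthonormal rows
    eigenvalues: np.ndarray  # (k,), nonincreasing, sample-variance scale
    n_training_samples: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_features(self) -> int:
        return self.components.shape[1]

    @property
    def model_id(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mean_vector))
        h.update(np.ascontiguousarray(self.components))
        return h.hexdigest()[:16]

    def explained_variance_ratio(self) -> np.ndarray:
        """Fraction of total retained variance per component."""
        total = self.eigenvalues.sum()
        if total == 0:
            raise DegenerateInputError("all eigenvalues are zero; no variance to apportion")
        return self.eigenvalues / total


@dataclass
class CoefficientMatrix:
    """Samples projected into a PCA subspace (the classifier's features)."""

    values: np.ndarray  # (n_samples, n_components)
    model_id: str = ""

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureRanking:
    """Per-component Fisher ratios and the descending-FDR ordering."""

    fdr_scores: np.ndarray  # (k,), >= 0 (may hold +inf)
    order: np.ndarray  # permutation: order[0] is the most discriminative component
    class_means: np.ndarray = field(default=None)  # type: ignore[assignment]  # (2, k): row 0 class −1, row 1 class +1
    class_variances: np.ndarray = field(default=None)  # type: ignore[assignment]


def fit_pca(X, max_components: int | None = None) -> PCAModel:
    """Fit the PCA subspace of a training matrix (FeatureMatrix or array).

    Components whose eigenvalue falls below ``1e-10`` of the largest are
    dropped as numerically zero; with n training samples at most n−1
    components can carry variance, so a cohort of 31 yields 30.
    """
    values = _as_matrix(X)
    n = values.shape[0]
    if n < 2:
        raise DegenerateInputError(f"PCA needs at least 2 samples, got {n}")
    mean = values.mean(axis=0)
    centered = values - mean
    # thin SVD: U (n×r), s (r,), Vt (r×p) with r = min(n, p)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    limit = min(n - 1, eigenvalues.size)
    if max_components is not None:
        limit = min(limit, max_components)
    keep = eigenvalues[:limit] > EIGENVALUE_RTOL * (eigenvalues[0] if eigenvalues.size else 0.0)
    components = vt[:limit][keep]
    eigenvalues = eigenvalues[:limit][keep]
    # sign convention: largest-|entry| of each component positive
    if components.size:
        flip = components[np.arange(components.shape[0]), np.abs(components).argmax(axis=1)] < 0
        components[flip] *= -1.0
    return PCAModel(
        mean_vector=mean,
        components=components,
        eigenvalues=eigenvalues,
        n_training_samples=n,
    )


def project(model: PCAModel, X) -> CoefficientMatrix:
    """Coefficients of (possibly unseen) samples: ``(X − mean) @ componentsᵀ``."""
    values = _as_matrix(X)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != model.n_features:
        raise ShapeMismatchError(
            f"samples have {values.shape[1]} features, model expects {model.n_features}"
        )
    return CoefficientMatrix(values=(values - model.mean_vector) @ model.components.T, model_id=model.model_id)


def back_project(
    model: PCAModel,
    coefficients,
    component_subset: np.ndarray | list[int] | None = None,
    include_mean: bool = False,
) -> np.ndarray:
    """Reconstruct voxel-space rows from coefficients over a component subset.

    With ``include_mean`` the training mean is added back (an image-like
    reconstruction); without it the result is the mean-free linear
    combination, which is what discriminative maps need.
    """
    coeffs = _as_matrix(coefficients)
    if coeffs.ndim == 1:
        coeffs = coeffs[None, :]
    if component_subset is None:
        subset = np.arange(model.n_components)
    else:
        subset = np.asarray(component_subset, dtype=int)
        if subset.size and (subset.min() < 0 or subset.max() >= model.n_components):
            raise IndexError(
                f"component_subset out of range: model has {model.n_components} components, got {subset.tolist()}"
            )
    if coeffs.shape[1] != subset.size:
        raise ShapeMismatchError(f"got {coeffs.shape[1]} coefficient columns for {subset.size} selected components")
    recon = coeffs @ model.components[subset]
    if include_mean:
        recon = recon + model.mean_vector
    return recon


def fdr_rank(coefficients, labels) -> FeatureRanking:
    """Rank components by Fisher Discriminant Ratio, descending.

    Labels are {−1, +1}; each class needs at least 2 samples for its
    variance.  A component with equal class means scores 0 however large the
    variances; one with distinct means but zero pooled variance separates the
    classes perfectly and scores +inf, ranking first.  Ties break toward the
    lower component index.
    """
    values = _as_matrix(coefficients)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DegenerateInputError(f"FDR ranking needs exactly 2 classes, got labels {classes.tolist()}")
    masks = [labels == c for c in classes]
    for c, m in zip(classes, masks):
        if m.sum() < 2:
            raise DegenerateInputError(f"class {c} has {int(m.sum())} sample(s); need >= 2 for a variance")
    means = np.vstack([values[m].mean(axis=0) for m in masks])
    variances = np.vstack([values[m].var(axis=0, ddof=1) for m in masks])
    num = (means[0] - means[1]) ** 2
    den = variances[0] + variances[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    order = np.argsort(-fdr, kind="stable")
    return FeatureRanking(fdr_scores=fdr, order=order, class_means=means, class_variances=variances)
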