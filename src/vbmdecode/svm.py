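"""Linear soft-margin support-vector classification.

The decision function is kept in its dual form

    y(x) = Σ_n a_n · t_n · ⟨x, x_n⟩ + b

with a_n ∈ [0, C] the per-training-sample dual weights (nonzero only at
support vectors), t_n ∈ {±1} the labels and b the bias.  The quadratic
program is solved by scikit-learn's SVC; this module stores the dual
solution explicitly and evaluates y(x) from it, so the weights that feed the
discriminative maps are first-class.  Only the linear kernel is supported —
it is the only kernel under which the primal weight vector
``w = Σ a_n t_n x_n`` exists and voxel maps can be formed.

Ties at y(x) = 0 predict +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import DegenerateInputError, ShapeMismatchError

__all__ = ["LinearSVMModel", "train", "decision_value", "predict"]


@dataclass
class LinearSVMModel:
    dual_weights: np.ndarray  # a_n >= 0, one per support vector
    support_labels: np.ndarray  # t_n in {±1}
    support_samples: np.ndarray  # (n_sv, n_features) coefficient vectors
    bias: float
    C: float
    kernel: str = "linear"

    @property
    def n_features(self) -> int:
        return self.support_samples.shape[1]

    @property
    def primal_weights(self) -> np.ndarray:
        """w = Σ a_n t_n x_n; reproduces y(x) = ⟨w, x⟩ + b for a linear kernel."""
        return (self.dual_weights * self.support_labels) @ self.support_samples

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dual_weights": self.dual_weights.tolist(),
            "support_labels": self.support_labels.tolist(),
            "support_samples": self.support_samples.tolist(),
            "bias": self.bias,
            "C": self.C,
            "kernel": self.kernel,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearSVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            dual_weights=np.asarray(d["dual_weights"], dtype=float),
            support_labels=np.asarray(d["support_labels"], dtype=int),
            support_samples=np.asarray(d["support_samples"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            kernel=d["kernel"],
        )


def train(coefficients, labels, C: float = 1.0, kernel: str = "linear") -> LinearSVMModel:
    """Fit the maximum-margin hyperplane at soft-margin cost C.

    Deterministic for fixed input.  C defaults to 1; a large C approaches the
    hard-margin classifier on separable data.
    """
    if kernel != "linear":
        raise ValueError(f"only the linear kernel is supported, got {kernel!r}")
    X = np.asarray(getattr(coefficients, "values", coefficients), dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("training coefficients contain non-finite values")
    if np.unique(y).size < 2:
        raise DegenerateInputError("training needs both classes present")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    # tight KKT tolerance so mirrored problems (label swap, sign flips)
    # yield mirrored solutions to numerical precision
    clf = SVC(kernel="linear", C=C, tol=1e-10)
    clf.fit(X, y)
    # sklearn orders classes ascending, so dual_coef_ rows are a_n * t_n
    # with t_n the true label of each support vector; recover a_n = |coef|.
    signed = clf.dual_coef_[0]
    support_labels = y[clf.support_]
    return LinearSVMModel(
        dual_weights=np.abs(signed),
        support_labels=support_labels,
        support_samples=X[clf.support_],
        bias=float(clf.intercept_[0]),
        C=C,
    )


def decision_value(model: LinearSVMModel, x) -> np.ndarray | float:
    """Evaluate y(x) from the dual form; scalar in, scalar out."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 1
    if scalar:
        arr = arr[None, :]
    if arr.shape[1] != model.n_features:
        raise ShapeMismatchError(f"x has {arr.shape[1]} features, model expects {model.n_features}")
    y = arr @ model.support_samples.T @ (model.dual_weights * model.support_labels) + model.bias
    return float(y[0]) if scalar else y


def predict(model: LinearSVMModel, x) -> np.ndarray | int:
    """sign(y(x)) with the y = 0 tie resolved to class +1."""
    y = decision_value(model, x)
    if np.isscalar(y):
        return 1 if y >= 0 else -1
    return np.where(np.asarray(y) >= 0, 1, -1)
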