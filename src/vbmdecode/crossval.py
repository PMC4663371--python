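"""Stratified k-fold evaluation of the PCA → FDR → SVM pipeline.

Each fold fits the whole feature-extraction chain on its training subjects
only — PCA subspace, Fisher-ratio ranking — then projects the held-out
subjects into that subspace and classifies them with an SVM trained on the
first k ranked coefficients.  Nothing fitted ever sees a test subject, so
the evaluation is leakage-free.

Metrics are computed on predictions *pooled* across folds: the metric
formulas count images, and pooling is the only reading under which a single
total N exists.  Accuracy, specificity and sensitivity are reported as a
function of k, the number of employed coefficients.

Two denominator conventions are provided for specificity/sensitivity:

* ``standard``:   Specificity = A_CC / (A_CC + A_IC),  Sensitivity = B_CC / (B_CC + B_IC)
* ``as-printed``: Specificity = A_CC / (A_CC + B_IC),  Sensitivity = B_CC / (B_CC + A_IC)

where A is the first group (label −1, controls) and B the second (label +1,
patients); CC/IC = correctly/incorrectly classified.  The second convention
reproduces a formula set sometimes seen in print whose denominators mix the
two groups; the default is the standard one.  Accuracy = N_CC / N always.
Undefined ratios (zero denominator) are returned as NaN, never as a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pca as _pca
from . import svm as _svm
from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "FoldResult",
    "CVResult",
    "stratified_partition",
    "run_fold",
    "compute_metrics",
    "run_cv",
]

CONVENTIONS = ("standard", "as-printed")


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each subject to exactly one of ``n_subsets`` subsets."""

    n_subsets: int
    assignments: np.ndarray  # (n_subjects,) subset index per subject
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_partition(labels, n_subsets: int, seed: int) -> FoldPlan:
    """Split subjects into ``n_subsets`` subsets preserving class proportions.

    Within each class the subjects are shuffled (seeded) and dealt round-robin
    onto the subsets; the deal pointer continues across classes so no subset
    is left empty even when a class has fewer members than there are subsets.
    Per-class subset sizes therefore differ by at most one.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n_subsets < 2:
        raise ConfigurationError(f"n_subsets must be >= 2, got {n_subsets}")
    if n_subsets > n:
        raise ConfigurationError(f"n_subsets={n_subsets} exceeds number of subjects ({n})")
    classes = np.unique(labels)
    if classes.size < 2:
        raise DegenerateInputError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    pointer = 0
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i in idx:
            assignments[i] = pointer % n_subsets
            pointer += 1
    return FoldPlan(n_subsets=n_subsets, assignments=assignments, seed=seed)


@dataclass
class ConfusionCounts:
    """Image counts over the two groups; A = first group (−1), B = second (+1)."""

    A_CC: int = 0
    A_IC: int = 0
    B_CC: int = 0
    B_IC: int = 0

    @property
    def N(self) -> int:
        return self.A_CC + self.A_IC + self.B_CC + self.B_IC

    @property
    def N_CC(self) -> int:
        return self.A_CC + self.B_CC

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.A_CC + other.A_CC,
            self.A_IC + other.A_IC,
            self.B_CC + other.B_CC,
            self.B_IC + other.B_IC,
        )

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionCounts":
        labels = np.asarray(labels)
        predictions = np.asarray(predictions)
        a = labels == -1
        b = labels == +1
        correct = labels == predictions
        return cls(
            A_CC=int((a & correct).sum()),
            A_IC=int((a & ~correct).sum()),
            B_CC=int((b & correct).sum()),
            B_IC=int((b & ~correct).sum()),
        )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(counts: ConfusionCounts, convention: str = "standard") -> tuple[float, float, float]:
    """(Accuracy, Specificity, Sensitivity) under the chosen convention."""
    if convention not in CONVENTIONS:
        raise ConfigurationError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    if counts.N == 0:
        raise DegenerateInputError("no classified images: N = 0")
    accuracy = counts.N_CC / counts.N
    if convention == "standard":
        specificity = _ratio(counts.A_CC, counts.A_CC + counts.A_IC)
        sensitivity = _ratio(counts.B_CC, counts.B_CC + counts.B_IC)
    else:
        specificity = _ratio(counts.A_CC, counts.A_CC + counts.B_IC)
        sensitivity = _ratio(counts.B_CC, counts.B_CC + counts.A_IC)
    return accuracy, specificity, sensitivity


@dataclass
class FoldResult:
    predictions: np.ndarray  # (n_test,) in {±1}
    decision_values: np.ndarray
    counts: ConfusionCounts
    n_components_available: int
    k_used: int
    pca_model: "_pca.PCAModel" = field(repr=False, default=None)  # type: ignore[assignment]
    ranking: "_pca.FeatureRanking" = field(repr=False, default=None)  # type: ignore[assignment]
    svm_model: "_svm.LinearSVMModel" = field(repr=False, default=None)  # type: ignore[assignment]


def run_fold(train_matrix, train_labels, test_matrix, test_labels, k: int, C: float = 1.0) -> FoldResult:
    """One train/test round: PCA + FDR on training only, SVM on top-k coefficients.

    If the training matrix yields fewer than ``k`` components the fold uses
    all it has and records it (``k_used < k``); small folds cannot always
    supply the requested coefficient count.
    """
    model = _pca.fit_pca(train_matrix)
    train_coeffs = _pca.project(model, train_matrix)
    ranking = _pca.fdr_rank(train_coeffs, train_labels)
    k_used = min(k, model.n_components)
    top = ranking.order[:k_used]
    clf = _svm.train(train_coeffs.values[:, top], train_labels, C=C)
    test_coeffs = _pca.project(model, test_matrix)
    decisions = _svm.decision_value(clf, test_coeffs.values[:, top])
    preds = np.where(np.asarray(decisions) >= 0, 1, -1)
    return FoldResult(
        predictions=preds,
        decision_values=np.asarray(decisions),
        counts=ConfusionCounts.from_predictions(test_labels, preds),
        n_components_available=model.n_components,
        k_used=k_used,
        pca_model=model,
        ranking=ranking,
        svm_model=clf,
    )


@dataclass
class CVResult:
    """Per-k pooled metric curves plus the winning k and full provenance."""

    per_k: pd.DataFrame  # columns: k, accuracy, specificity, sensitivity
    best_k: int
    best_metrics: tuple[float, float, float]
    fold_plan: FoldPlan
    predictions: np.ndarray  # (k_max, n_subjects), pooled test predictions per k
    labels: np.ndarray
    convention: str
    C: float
    events: list[str] = field(default_factory=list)

    @property
    def k_max(self) -> int:
        return int(self.per_k["k"].max())

    def _row_for_k(self, k: int) -> int:
        rows = np.flatnonzero(self.per_k["k"].to_numpy() == k)
        if rows.size == 0:
            raise KeyError(f"k={k} was not evaluated")
        return int(rows[0])

    def counts_for_k(self, k: int) -> ConfusionCounts:
        return ConfusionCounts.from_predictions(self.labels, self.predictions[self._row_for_k(k)])

    def accuracy_at(self, k: int) -> float:
        return float(self.per_k["accuracy"].iloc[self._row_for_k(k)])

    def to_csv(self, path) -> None:
        self.per_k.to_csv(path, index=False, float_format="%.6f")

    def summary(self) -> dict:
        acc, spec, sens = self.best_metrics
        return {
            "n_subsets": self.fold_plan.n_subsets,
            "seed": self.fold_plan.seed,
            "C": self.C,
            "convention": self.convention,
            "best_k": self.best_k,
            "best_accuracy": acc,
            "best_specificity": spec,
            "best_sensitivity": sens,
            "events": self.events,
        }


def run_cv(
    features,
    labels,
    n_subsets: int = 20,
    k_range=None,
    C: float = 1.0,
    seed: int = 0,
    convention: str = "standard",
) -> CVResult:
    """Full stratified CV: pooled metric curves as a function of k.

    ``features`` is a FeatureMatrix (or plain subjects × voxels array).  For
    each fold the PCA/FDR chain is fitted once and the SVM retrained per k;
    predictions are pooled over folds into one confusion table per k.
    ``k_range`` defaults to 1 … (largest component count any fold offers).
    The best k maximizes pooled accuracy; ties go to the smallest k.
    """
    X = np.asarray(getattr(features, "values", features), dtype=float)
    labels = np.asarray(labels, dtype=int)
    plan = stratified_partition(labels, n_subsets, seed)

    # per fold: fit once, sweep k
    fold_fits = []
    for f in range(plan.n_subsets):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        model = _pca.fit_pca(X[tr])
        coeffs = _pca.project(model, X[tr])
        ranking = _pca.fdr_rank(coeffs, labels[tr])
        test_coeffs = _pca.project(model, X[te])
        fold_fits.append((tr, te, model, coeffs, ranking, test_coeffs))

    max_available = max(fit[2].n_components for fit in fold_fits)
    if k_range is None:
        k_values = list(range(1, max_available + 1))
    else:
        k_values = sorted(set(int(k) for k in k_range))
        if not k_values or k_values[0] < 1:
            raise ConfigurationError(f"k_range must contain positive integers, got {k_range}")

    events: list[str] = []
    n = labels.size
    predictions = np.zeros((len(k_values), n), dtype=int)
    for f, (tr, te, model, coeffs, ranking, test_coeffs) in enumerate(fold_fits):
        for row, k in enumerate(k_values):
            k_used = min(k, model.n_components)
            if k_used < k and k == k_values[-1]:
                events.append(
                    f"fold {f}: requested k={k} but only {model.n_components} components available; used all"
                )
            top = ranking.order[:k_used]
            clf = _svm.train(coeffs.values[:, top], labels[tr], C=C)
            decisions = np.asarray(_svm.decision_value(clf, test_coeffs.values[:, top]))
            predictions[row, te] = np.where(decisions >= 0, 1, -1)

    rows = []
    for row, k in enumerate(k_values):
        counts = ConfusionCounts.from_predictions(labels, predictions[row])
        acc, spec, sens = compute_metrics(counts, convention)
        rows.append({"k": k, "accuracy": acc, "specificity": spec, "sensitivity": sens})
    per_k = pd.DataFrame(rows)

    best_row = per_k.loc[per_k["accuracy"].idxmax()]  # idxmax: first max → smallest k
    best_k = int(best_row["k"])
    best = (float(best_row["accuracy"]), float(best_row["specificity"]), float(best_row["sensitivity"]))
    return CVResult(
        per_k=per_k,
        best_k=best_k,
        best_metrics=best,
        fold_plan=plan,
        predictions=predictions,
        labels=labels,
        convention=convention,
        C=C,
        events=events,
    )
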