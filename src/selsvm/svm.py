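"""RBF-kernel SVM training with the 2-sigma^2 kernel convention.

The kernel is K(x, y) = exp(-||x - y||^2 / (2 sigma^2)).  The backing
solver (libsvm via scikit-learn) uses a gamma parameterisation, so it
is wrapped with gamma = 1 / (2 sigma^2); the sigma grid values 0.4-0.6
are meaningless under any other convention.  Training uses a hard
margin (C = 100000 by default) and sigma is selected by stratified
5-fold cross-validation, maximising mean MCC with ties broken toward
the smaller sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .datasets import FoldAssignment, LabeledDataset, stratified_kfold
from .errors import ModelError
from .features import ScalerParams, apply_scaler

DEFAULT_C = 100000.0
DEFAULT_SIGMA_GRID = (0.4, 0.5, 0.6)


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray | float:
    """Gaussian kernel exp(-||x-y||^2 / (2 sigma^2)).

    Accepts single vectors or 2-D row matrices; returns a scalar or the
    Gram matrix K[i, j] = K(x_i, y_j).
    """
    if sigma <= 0:
        raise ModelError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 1 and y.ndim == 1
    X = np.atleast_2d(x)
    Y = np.atleast_2d(y)
    if X.shape[1] != Y.shape[1]:
        raise ModelError("kernel arguments must share a dimension")
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Y * Y, axis=1)[None, :]
        - 2.0 * (X @ Y.T)
    )
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / (2.0 * sigma * sigma))
    return float(K[0, 0]) if scalar else K


@dataclass
class SvmModel:
    """Trained kernel classifier in explicit dual form.

    The decision function is f(x) = sum_k alpha_k K(x_k, x) + b where
    alpha_k are the signed dual coefficients (y_k * |alpha_k|, bounded
    by C in magnitude) over the support vectors x_k.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # signed: y_k * alpha_k
    intercept: float
    sigma: float
    C: float
    task: str
    descriptor_names: list[str]
    scaler: ScalerParams | None = None
    sample_alpha: np.ndarray | None = None  # per-training-sample alpha >= 0
    support_idx: np.ndarray | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Explicit f(x) over scaled inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            return np.zeros(0)
        K = rbf_kernel(X, self.support_vectors, self.sigma)
        return K @ self.dual_coef + self.intercept


def train_svm(dataset: LabeledDataset, C: float = DEFAULT_C, sigma: float = 0.5) -> SvmModel:
    """Fit a hard-margin RBF SVM on a labeled (scaled) dataset."""
    if sigma <= 0:
        raise ModelError("sigma must be positive")
    gamma = 1.0 / (2.0 * sigma * sigma)
    clf = SVC(C=C, kernel="rbf", gamma=gamma, cache_size=256, tol=1e-3)
    try:
        clf.fit(dataset.X, dataset.y)
    except Exception as exc:
        raise ModelError(f"SVM training failed for task {dataset.task!r}: {exc}") from exc
    # libsvm orders classes ascending: classes_ = [-1, 1]; dual_coef_ is
    # y_k * alpha_k and decision_function is positive for class +1.
    dual = clf.dual_coef_.ravel().astype(float)
    alpha = np.zeros(len(dataset.y), dtype=float)
    alpha[clf.support_] = np.abs(dual)
    return SvmModel(
        support_vectors=clf.support_vectors_.astype(float),
        dual_coef=dual,
        intercept=float(clf.intercept_[0]),
        sigma=float(sigma),
        C=float(C),
        task=dataset.task,
        descriptor_names=list(dataset.descriptor_names),
        scaler=dataset.scaler,
        sample_alpha=alpha,
        support_idx=clf.support_.copy(),
    )


def predict(
    model: SvmModel,
    X: np.ndarray,
    descriptor_names: list[str] | None = None,
    prescaled: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (+/-1) and decision values for a descriptor matrix.

    Raw inputs are scaled with the model's own scaler; pass
    ``prescaled=True`` for matrices already in the model's scaled
    space.  Descriptor provenance is checked when names are supplied.
    """
    if descriptor_names is not None and list(descriptor_names) != list(model.descriptor_names):
        raise ModelError("descriptor names do not match the model's training descriptors")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    if not prescaled:
        if model.scaler is None:
            raise ModelError("model has no scaler; pass prescaled inputs")
        X = apply_scaler(model.scaler, X)
    elif X.shape[1] != model.support_vectors.shape[1]:
        raise ModelError("input dimension does not match model")
    f = model.decision_function(X)
    labels = np.where(f >= 0, 1, -1)
    return labels, f


@dataclass
class CvReport:
    """Per-sigma cross-validation summary and the selected sigma."""

    per_sigma: dict[float, dict]
    selected_sigma: float
    criterion: str
    k: int
    seed: int


def _fold_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == -1) & (y_true == -1)))
    fp = int(np.sum((y_pred == 1) & (y_true == -1)))
    fn = int(np.sum((y_pred == -1) & (y_true == 1)))
    return tp, tn, fp, fn


def _mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _q(tp: int, tn: int, fp: int, fn: int) -> float:
    n = tp + tn + fp + fn
    return (tp + tn) / n if n else 0.0


_CRITERIA = {"mcc": _mcc, "q": _q}


def select_sigma_cv(
    dataset: LabeledDataset,
    grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    k: int = 5,
    seed: int = 0,
    criterion: str = "mcc",
    C: float = DEFAULT_C,
    folds: FoldAssignment | None = None,
) -> CvReport:
    """Grid-search sigma by stratified k-fold CV.

    The selected sigma maximises the mean per-fold criterion (default
    MCC); exact ties go to the smaller sigma.  The same fold assignment
    is reused across the grid so the comparison is paired.
    """
    if not grid:
        raise ModelError("sigma grid must be nonempty")
    if criterion not in _CRITERIA:
        raise ModelError(f"unknown CV criterion {criterion!r}")
    score_fn = _CRITERIA[criterion]
    folds = folds or stratified_kfold(dataset, k=k, seed=seed)
    per_sigma: dict[float, dict] = {}
    for sigma in grid:
        gamma = 1.0 / (2.0 * sigma * sigma)
        fold_counts = []
        scores = []
        for fold in range(folds.k):
            tr, te = folds.train_test(fold)
            if len(np.unique(dataset.y[tr])) < 2 or len(te) == 0:
                raise ModelError(f"fold {fold} has an empty class; cannot cross-validate")
            clf = SVC(C=C, kernel="rbf", gamma=gamma, cache_size=256)
            clf.fit(dataset.X[tr], dataset.y[tr])
            pred = clf.predict(dataset.X[te])
            counts = _fold_confusion(dataset.y[te], pred)
            fold_counts.append(counts)
            scores.append(score_fn(*counts))
        per_sigma[float(sigma)] = {
            "fold_confusions": fold_counts,
            "fold_scores": scores,
            "mean_score": float(np.mean(scores)),
        }
    best = max(sorted(per_sigma), key=lambda s: (per_sigma[s]["mean_score"], -s))
    return CvReport(per_sigma, float(best), criterion, folds.k, seed)
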