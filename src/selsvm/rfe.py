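"""Gaussian-kernel SVM recursive feature elimination.

Descriptors are ranked by the variation of the SVM dual objective
caused by removing one descriptor with the dual coefficients held
fixed:

    DJ(i) = 1/2 alpha^T H alpha - 1/2 alpha^T H(-i) alpha

where H has elements H_kj = y_k y_j exp(-||x_k - x_j||^2 / (2 sigma^2))
and H(-i) is computed with descriptor i deleted from every vector
(0 <= alpha_k <= C).  Each iteration trains the SVM on the surviving
descriptors, scores every descriptor, removes the m with the smallest
scores (m = 4 by default), records the 5-fold CV accuracy, and repeats
until no descriptors remain; the loop runs once per sigma in the grid.
Removing a descriptor shrinks squared distances, so H(-i) is obtained
from H by the elementwise factor exp(diff_i^2 / (2 sigma^2)) — a
constant descriptor leaves H unchanged and has DJ exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .datasets import LabeledDataset, stratified_kfold
from .errors import ModelError
from .svm import DEFAULT_C, DEFAULT_SIGMA_GRID, train_svm


@dataclass
class KernelLabelMatrix:
    """The label-weighted Gaussian kernel matrix H (optionally H(-i))."""

    H: np.ndarray
    sigma: float
    excluded_descriptor: int | None = None


def build_H(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float,
    excluded_descriptor: int | None = None,
) -> KernelLabelMatrix:
    """H_kj = y_k y_j exp(-||x_k - x_j||^2 / (2 sigma^2)).

    ``excluded_descriptor`` drops that column of X before the distance
    computation, giving H(-i).
    """
    if sigma <= 0:
        raise ModelError("sigma must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ModelError("X and y must align")
    if excluded_descriptor is not None:
        X = np.delete(X, excluded_descriptor, axis=1)
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(X * X, axis=1)[None, :]
        - 2.0 * (X @ X.T)
    )
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / (2.0 * sigma * sigma))
    return KernelLabelMatrix(np.outer(y, y) * K, sigma, excluded_descriptor)


def dj_scores(alpha: np.ndarray, X: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """DJ(i) for every current descriptor, with alpha held fixed.

    ``alpha`` is the per-sample non-negative dual coefficient vector of
    the trained model (zero off the support set).
    """
    alpha = np.asarray(alpha, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha.shape[0] != X.shape[0]:
        raise ModelError("alpha and X must align")
    # alpha^T H alpha = s^T K s with s = alpha * y (H = yy^T ∘ K)
    H = build_H(X, y, sigma).H
    K = H * np.outer(y, y)  # y in {+-1} so yy^T ∘ H recovers K
    s = alpha * y
    base = float(s @ K @ s)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    scores = np.empty(X.shape[1])
    for i in range(X.shape[1]):
        diff = X[:, i][:, None] - X[:, i][None, :]
        K_minus = K * np.exp(diff * diff * inv2s2)
        scores[i] = 0.5 * base - 0.5 * float(s @ K_minus @ s)
    return scores


@dataclass
class RfeIteration:
    removed: list[str]
    dj: dict[str, float]
    cv_accuracy: float


@dataclass
class RfeResult:
    """Elimination order and ranking for one sigma.

    ``elimination_order`` lists descriptors first-removed to
    last-removed; the final ranking is its reverse, with descriptors
    removed in the same batch sharing a rank band.
    """

    sigma: float
    m: int
    elimination_order: list[str]
    rank_band: dict[str, int]  # 0 = last-surviving band
    iterations: list[RfeIteration] = field(default_factory=list)

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean([it.cv_accuracy for it in self.iterations]))

    def top_ranked(self, band: int = 0) -> list[str]:
        return sorted(n for n, b in self.rank_band.items() if b <= band)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, sigma: float, C: float, k: int, seed: int,
                 names: list[str], scaler) -> float:
    ds = LabeledDataset(X, y, [f"i{j}" for j in range(len(y))], "rfe:cv", names, scaler)
    folds = stratified_kfold(ds, k=k, seed=seed)
    gamma = 1.0 / (2.0 * sigma * sigma)
    accs = []
    for fold in range(k):
        tr, te = folds.train_test(fold)
        if len(np.unique(y[tr])) < 2 or len(te) == 0:
            raise ModelError("empty class in RFE cross-validation fold")
        clf = SVC(C=C, kernel="rbf", gamma=gamma, cache_size=256)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def rfe_rank(
    dataset: LabeledDataset,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    m: int = 4,
    k: int = 5,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> tuple[dict[float, RfeResult], float]:
    """Run the elimination loop for every sigma in the grid.

    Returns per-sigma results and the selected sigma (best mean CV
    accuracy over iterations; ties -> smaller sigma).  Within an
    iteration, ties among equal smallest DJ scores are broken by
    removing the larger column index first.
    """
    if m < 1:
        raise ModelError("m must be >= 1")
    if not sigma_grid:
        raise ModelError("sigma grid must be nonempty")
    results: dict[float, RfeResult] = {}
    for sigma in sigma_grid:
        remaining = list(range(len(dataset.descriptor_names)))
        order: list[str] = []
        iterations: list[RfeIteration] = []
        while remaining:
            X = dataset.X[:, remaining]
            names = [dataset.descriptor_names[j] for j in remaining]
            sub = LabeledDataset(
                X, dataset.y, list(dataset.compound_ids),
                dataset.task, names, dataset.scaler,
            )
            model = train_svm(sub, C=C, sigma=sigma)
            cv_acc = _cv_accuracy(X, dataset.y, sigma, C, k, seed, names, dataset.scaler)
            scores = dj_scores(model.sample_alpha, X, dataset.y, sigma)
            n_remove = min(m, len(remaining))
            # smallest DJ first; ties -> larger column index removed first
            rank = sorted(range(len(remaining)), key=lambda j: (scores[j], -remaining[j]))
            batch_local = rank[:n_remove]
            removed_names = [names[j] for j in batch_local]
            iterations.append(
                RfeIteration(removed_names, dict(zip(names, map(float, scores))), cv_acc)
            )
            order.extend(removed_names)
            removed_global = {remaining[j] for j in batch_local}
            remaining = [j for j in remaining if j not in removed_global]
        # rank bands: last-removed batch is band 0
        band_of: dict[str, int] = {}
        n_iter = len(iterations)
        for it_idx, it in enumerate(iterations):
            for name in it.removed:
                band_of[name] = n_iter - 1 - it_idx
        results[float(sigma)] = RfeResult(float(sigma), m, order, band_of, iterations)
    best = max(
        sorted(results), key=lambda s: (results[s].mean_cv_accuracy, -s)
    )
    return results, float(best)
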