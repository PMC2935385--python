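"""Nearest-shrunken-centroids (PAM-style) classification.

The classifier ranks features by a penalized t-statistic

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s_0)),   m_k = sqrt(1/n_k - 1/n)

where xbar_ik is the class-k centroid of feature i, xbar_i the overall
centroid, s_i the pooled within-class standard deviation and s_0 the median
of the s_i (a variance-stabilizing offset).  Soft-thresholding at a
shrinkage level Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0),

moves class centroids toward the overall centroid and zeroes out features
with no class signal; a feature "survives" when any class keeps d'_ik != 0.
Prediction assigns a sample x* to the class minimizing the discriminant

    delta_k(x*) = sum_i (x*_i - xbar'_ik)^2 / (s_i + s_0)^2 - 2 log pi_k

with class priors pi_k = n_k / n, and reports softmax posteriors
proportional to exp(-delta_k / 2).  Delta is chosen by stratified k-fold
cross-validation, preferring the *largest* Delta (sparsest model) attaining
the minimal CV misclassification count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class NSCModel:
    feature_ids: list
    classes: list
    overall_centroid: np.ndarray     # (p,)
    class_centroids: np.ndarray      # (p, K) unshrunken
    shrunken_centroids: np.ndarray   # (p, K)
    s: np.ndarray                    # pooled within-class s.d., (p,)
    s0: float
    priors: np.ndarray               # (K,)
    class_counts: np.ndarray
    delta: float
    d: np.ndarray                    # penalized t-statistics, (p, K)
    d_shrunk: np.ndarray             # (p, K)

    @property
    def surviving_features(self) -> list:
        mask = (self.d_shrunk != 0).any(axis=1)
        return [f for f, m in zip(self.feature_ids, mask) if m]


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def nsc_fit(X: pd.DataFrame, y, delta: float = 0.0) -> NSCModel:
    """Fit shrunken centroids on a features x samples matrix.

    ``y`` gives one class label per sample (column).  Every class needs at
    least 2 samples so the pooled within-class variance is defined.
    """
    y = np.asarray(y)
    if y.shape[0] != X.shape[1]:
        raise ValueError("y must label the columns of X")
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    V = X.to_numpy(dtype=float)
    n = V.shape[1]
    counts = np.array([(y == c).sum() for c in classes])
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")

    overall = V.mean(axis=1)
    cents = np.column_stack([V[:, y == c].mean(axis=1) for c in classes])
    # pooled within-class variance with n - K degrees of freedom
    ss = np.zeros(V.shape[0])
    for k, c in enumerate(classes):
        block = V[:, y == c] - cents[:, [k]]
        ss += (block * block).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    m = np.sqrt(1.0 / counts - 1.0 / n)
    denom = np.outer(s + s0, m)
    d = (cents - overall[:, None]) / denom
    d_shrunk = _soft_threshold(d, delta)
    shrunken = overall[:, None] + denom * d_shrunk
    return NSCModel(
        feature_ids=list(X.index), classes=classes, overall_centroid=overall,
        class_centroids=cents, shrunken_centroids=shrunken, s=s, s0=s0,
        priors=counts / n, class_counts=counts, delta=delta, d=d, d_shrunk=d_shrunk,
    )


def nsc_predict(model: NSCModel, X: pd.DataFrame):
    """Predict class labels and posterior probabilities for columns of X.

    Features must match the model exactly (no imputation); rows are
    reordered by id if needed.
    """
    if set(X.index) != set(model.feature_ids):
        missing = set(model.feature_ids) - set(X.index)
        raise ValueError(f"feature mismatch; missing {len(missing)} model features")
    V = X.loc[model.feature_ids].to_numpy(dtype=float)
    scale = (model.s + model.s0)[:, None]
    # discriminant per class: standardized distance to shrunken centroid - 2 log prior
    disc = np.empty((V.shape[1], len(model.classes)))
    for k in range(len(model.classes)):
        z = (V - model.shrunken_centroids[:, [k]]) / scale
        disc[:, k] = (z * z).sum(axis=0) - 2.0 * np.log(model.priors[k])
    # softmax of -disc/2, stabilized
    w = -0.5 * disc
    w -= w.max(axis=1, keepdims=True)
    post = np.exp(w)
    post /= post.sum(axis=1, keepdims=True)
    labels = [model.classes[k] for k in disc.argmin(axis=1)]
    return (
        pd.Series(labels, index=X.columns, name="predicted"),
        pd.DataFrame(post, index=X.columns, columns=model.classes),
    )


@dataclass
class CVResult:
    delta_grid: np.ndarray
    cv_errors: np.ndarray            # misclassification count per delta
    n_features: np.ndarray           # surviving features of full-data fit per delta
    selected_delta: float
    model: NSCModel                  # refit on all data at selected delta
    confusion: pd.DataFrame          # true x predicted counts (full-data refit)
    per_class_correct: pd.Series
    success_rate: float


def nsc_cv(X: pd.DataFrame, y, delta_grid=None, folds: int = 10, seed: int = 0) -> CVResult:
    """Cross-validated shrinkage selection and full-data refit.

    Stratified folds (degrading gracefully when a class is smaller than the
    fold count); the selected Delta is the largest attaining minimal CV
    error, preferring sparser models.  The confusion matrix and success rate
    describe the refit model's resubstitution predictions, matching how a
    final locus classifier is reported.
    """
    y = np.asarray(y)
    if delta_grid is None:
        probe = nsc_fit(X, y, 0.0)
        delta_grid = np.linspace(0.0, np.abs(probe.d).max(), 30)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ValueError("empty delta grid")

    smallest = min(np.bincount(pd.factorize(y)[0]))
    n_splits = max(2, min(folds, smallest))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    errors = np.zeros(delta_grid.size)
    for train, test in skf.split(X.T, y):
        for gi, delta in enumerate(delta_grid):
            model = nsc_fit(X.iloc[:, train], y[train], delta)
            pred, _ = nsc_predict(model, X.iloc[:, test])
            errors[gi] += int((pred.to_numpy() != y[test]).sum())

    best = errors.min()
    selected = float(delta_grid[np.flatnonzero(errors == best)[-1]])  # sparsest
    model = nsc_fit(X, y, selected)
    full_d = np.abs(nsc_fit(X, y, 0.0).d)
    n_feat = np.array([int((full_d > d).any(axis=1).sum()) for d in delta_grid])
    pred, _ = nsc_predict(model, X)
    conf = pd.crosstab(pd.Series(y, index=X.columns, name="true"), pred).reindex(
        index=model.classes, columns=model.classes, fill_value=0
    )
    correct = pd.Series(np.diag(conf.to_numpy()), index=model.classes, name="correct")
    rate = float(np.trace(conf.to_numpy()) / conf.to_numpy().sum())
    return CVResult(
        delta_grid=delta_grid, cv_errors=errors, n_features=n_feat,
        selected_delta=selected, model=model, confusion=conf,
        per_class_correct=correct, success_rate=rate,
    )
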