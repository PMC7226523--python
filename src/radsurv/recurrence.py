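"""Boosted binary classification of local-regional recurrence.

The classifier is stagewise gradient boosting on the logistic loss
(sklearn's GradientBoostingClassifier); evaluation uses the Mann-Whitney
formulation of ROC AUC (score ties count 0.5) and a step-interpolated area
under the precision-recall curve (no linear interpolation between PR points,
which matters at small n; a constant scorer gets AUPRC equal to the
prevalence under this convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier


def roc_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney pairwise probability.

    AUC = P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) over all
    positive-negative pairs.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for AUC")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def pr_auprc(scores, labels) -> float:
    """Step-interpolated area under the precision-recall curve.

    Thresholds descend through the distinct scores; the area is
    sum_k (R_k - R_{k-1}) * P_k.  Ties in score move as one block.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("both classes must be present for AUPRC")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied-score block
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp = tp[distinct]
    fp = fp[distinct]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class BoostedClassifierModel:
    """Gradient-boosted recurrence classifier; scores are P(recurrence)."""

    n_stages: int = 100
    learning_rate: float = 0.1
    max_depth: int = 2
    min_samples_leaf: int = 3
    seed: int = 0
    _gbm: GradientBoostingClassifier | None = field(default=None, repr=False)
    _prevalence: float = 0.5
    feature_names_: list | None = None

    def fit(self, X, labels, feature_names=None) -> "BoostedClassifierModel":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(labels, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        self._prevalence = float(y.mean())
        if self.n_stages == 0 or len(np.unique(y)) < 2:
            self._gbm = None
            return self
        self._gbm = GradientBoostingClassifier(
            n_estimators=self.n_stages,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
        )
        self._gbm.fit(X, y)
        return self

    def predict_score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if self._gbm is None:
            return np.full(X.shape[0], self._prevalence)
        return self._gbm.predict_proba(X)[:, 1]

    def staged_scores(self, X):
        """Yield P(recurrence) after each boosting stage."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if self._gbm is None:
            yield np.full(X.shape[0], self._prevalence)
            return
        for proba in self._gbm.staged_predict_proba(X):
            yield proba[:, 1]


def fit_boosted_classifier(
    X, labels, hyperparams: dict | None = None, seed: int = 0, feature_names=None,
) -> BoostedClassifierModel:
    """Convenience constructor + fit."""
    model = BoostedClassifierModel(seed=seed, **(hyperparams or {}))
    return model.fit(X, labels, feature_names=feature_names)
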