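"""Boosted Cox risk modeling, Harrell concordance, Kaplan-Meier stratification.

The risk model is a stagewise gradient-boosting ensemble: each stage fits a
depth-limited regression tree to the gradient of the Efron partial
log-likelihood with respect to the per-sample risk score, then takes a
backtracking-scaled step, so the training loss is nonincreasing stage by
stage.  Higher predicted scores mean worse prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sklearn
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.tree import DecisionTreeRegressor

from ._cox import EfronData


# ---------------------------------------------------------------------------
# Harrell concordance
# ---------------------------------------------------------------------------

def concordance_index(risks, times, events) -> float:
    """Harrell concordance index of risk scores under right censoring.

    A pair (i, j) is comparable when the shorter observed time carries an
    event (including an event tied with a censoring time, where the censored
    patient is known to have survived at least as long); pairs tied in time
    with both events are non-comparable.  Concordant pairs (shorter time,
    higher risk) score 1, risk ties score 0.5.

    Raises
    ------
    ValueError
        If no comparable pair exists.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    ti = t[:, None]
    tj = t[None, :]
    ei = e[:, None]
    ej = e[None, :]
    comparable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pair: concordance undefined")
    ri = r[:, None]
    rj = r[None, :]
    score = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    return float(score[comparable].sum() / n_pairs)


# ---------------------------------------------------------------------------
# boosted Cox ensemble
# ---------------------------------------------------------------------------

@dataclass
class BoostedCoxModel:
    """Gradient-boosted Cox ensemble (relative risk scores, higher = worse).

    Hyperparameters
    ---------------
    n_stages : number of boosting stages (trees); 0 yields a constant model.
    learning_rate : shrinkage applied to each stage's step.
    max_depth : depth limit of the regression-tree base learners.
    min_samples_leaf : tree leaf size floor (guards tiny outer folds).
    seed : tree randomization seed; fits are deterministic given it.
    """

    n_stages: int = 100
    learning_rate: float = 0.1
    max_depth: int = 2
    min_samples_leaf: int = 3
    seed: int = 0
    trees_: list = field(default_factory=list, repr=False)
    scales_: list = field(default_factory=list, repr=False)
    train_loss_: list = field(default_factory=list, repr=False)
    feature_names_: list | None = None

    def fit(self, X, times, events, feature_names=None) -> "BoostedCoxModel":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if events.sum() < 1 or (X.shape[0] >= 2 and events.sum() < 2):
            raise ValueError("need at least 2 observed events to fit")
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        self.trees_, self.scales_, self.train_loss_ = [], [], []
        efron = EfronData(times, events)
        f = np.zeros(X.shape[0])
        nll = -efron.loglik(f)
        self.train_loss_.append(nll)
        rng = np.random.RandomState(self.seed)
        # sklearn's per-call validation dominates at this fit granularity
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        with sklearn.config_context(skip_parameter_validation=True, assume_finite=True):
            for _ in range(self.n_stages):
                grad = efron.gradient(f)  # ascent direction
                tree = DecisionTreeRegressor(
                    max_depth=self.max_depth,
                    min_samples_leaf=self.min_samples_leaf,
                    random_state=rng.randint(0, 2 ** 31 - 1),
                )
                tree.fit(X32, grad, check_input=False)
                h = tree.predict(X32, check_input=False).astype(np.float64)
                scale = self.learning_rate
                accepted = 0.0
                for _ in range(8):
                    nll_new = -efron.loglik(f + scale * h)
                    if nll_new <= nll:
                        accepted = scale
                        break
                    scale *= 0.5
                if accepted > 0.0:
                    f = f + accepted * h
                    nll = nll_new
                self.trees_.append(tree)
                self.scales_.append(accepted)
                self.train_loss_.append(nll)
        return self

    def predict(self, X) -> np.ndarray:
        """Cumulative ensemble risk score (log relative hazard scale)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[:, None]
        X = np.ascontiguousarray(X)
        f = np.zeros(X.shape[0])
        for tree, scale in zip(self.trees_, self.scales_):
            if scale != 0.0:
                f += scale * tree.predict(X, check_input=False)
        return f

    def staged_predict(self, X):
        """Yield the risk scores after each boosting stage (1..n_stages)."""
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=np.float32)))
        if X.shape[0] == 1 and len(self.trees_) and X.shape[1] != self.trees_[0].n_features_in_:
            X = X.T
        f = np.zeros(X.shape[0])
        for tree, scale in zip(self.trees_, self.scales_):
            if scale != 0.0:
                f = f + scale * tree.predict(X, check_input=False)
            yield f.copy()

    def to_json(self) -> dict:
        """Serializable model: hyperparameters, per-stage scales and the
        full tree structures (split feature/threshold/children/leaf value)."""
        trees = []
        for tree in self.trees_:
            t = tree.tree_
            trees.append(
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "value": t.value.reshape(-1).tolist(),
                }
            )
        return {
            "n_stages": self.n_stages,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "seed": self.seed,
            "stage_scales": list(self.scales_),
            "train_loss": list(self.train_loss_),
            "feature_names": self.feature_names_,
            "trees": trees,
        }


def fit_boosted_cox(
    X, times, events, hyperparams: dict | None = None, seed: int = 0,
    feature_names=None,
) -> BoostedCoxModel:
    """Convenience constructor + fit."""
    model = BoostedCoxModel(seed=seed, **(hyperparams or {}))
    return model.fit(X, times, events, feature_names=feature_names)


# ---------------------------------------------------------------------------
# Kaplan-Meier stratification
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray

    def evaluate(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        out = np.ones_like(grid, dtype=float)
        has = idx >= 0
        out[has] = self.survival[idx[has]]
        return out


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimate via lifelines."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return KMCurve(times=sf.index.to_numpy(dtype=float), survival=sf.iloc[:, 0].to_numpy())


@dataclass
class StratifiedKM:
    low: KMCurve
    high: KMCurve
    logrank_statistic: float
    logrank_p: float
    threshold: float
    n_low: int
    n_high: int


def stratify_and_km(risks, times, events) -> StratifiedKM:
    """Median-risk split into low/high groups, KM per group, 2-group log-rank.

    Patients with risk >= median(risk) form the high-risk group.

    Raises
    ------
    ValueError
        If either group is empty (e.g. all risk scores identical).
    """
    r = np.asarray(risks, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    thr = float(np.median(r))
    high = r >= thr
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty group")
    res = logrank_test(t[~high], t[high], e[~high], e[high])
    return StratifiedKM(
        low=km_curve(t[~high], e[~high]),
        high=km_curve(t[high], e[high]),
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        threshold=thr,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
    )


def average_km(curves: list[KMCurve], grid=None) -> KMCurve:
    """Pointwise average of KM curves on a common time grid.

    The default grid is the union of all curves' jump times.
    """
    if not curves:
        raise ValueError("no curves to average")
    if grid is None:
        grid = np.unique(np.concatenate([c.times for c in curves]))
    grid = np.asarray(grid, dtype=float)
    vals = np.vstack([c.evaluate(grid) for c in curves])
    return KMCurve(times=grid, survival=vals.mean(axis=0))
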