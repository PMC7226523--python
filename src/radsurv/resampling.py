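"""Nested cross-validation and three-model comparison.

Performance estimation uses an outer loop of repeated stratified k-fold
cross-validation (folds stratified on the event/label so small folds keep
events); hyperparameters are tuned per outer training set by an inner loop
of repeated stratified k-fold CV.  The stage count of the boosted models is
tuned cheaply through staged predictions: one fit at the largest candidate
stage count scores every smaller candidate.

All outer test-set metrics are collected (``outer_reps x outer_folds`` of
them); folds whose test set has no event or only one class are flagged and
excluded, and the bookkeeping invariant ``collected + flagged = reps x
folds`` always holds.  The same spec and seed reproduce identical folds, so
different models evaluated under one spec are compared on paired splits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .recurrence import BoostedClassifierModel, pr_auprc, roc_auc
from .survival import BoostedCoxModel, concordance_index

DEFAULT_PARAM_GRID = {"n_stages": [10, 25, 50], "learning_rate": [0.1], "max_depth": [2]}


@dataclass
class ResamplingSpec:
    """Outer/inner nested resampling configuration.

    The full-scale configuration is 500x3 outer / 100x3 inner; scaled-down
    specs (e.g. 50x3 / 10x3) are the default for desk-scale runs.
    """

    outer_reps: int = 50
    outer_folds: int = 3
    inner_reps: int = 10
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.outer_reps < 1 or self.inner_reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class ResamplingResult:
    """Distribution of outer test-set metrics for one model."""

    model_name: str
    metric_name: str
    spec: ResamplingSpec
    values: np.ndarray                  # collected metrics, flagged folds excluded
    n_flagged: int
    chosen_params: list[dict] = field(default_factory=list, repr=False)
    extra_metrics: dict = field(default_factory=dict, repr=False)
    fold_test_indices: list = field(default_factory=list, repr=False)
    fold_risks: list = field(default_factory=list, repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else float("nan")

    def average_patient_risk(self, n_patients: int) -> np.ndarray:
        """Per-patient risk averaged over all outer test sets containing the
        patient (used for median-risk KM stratification)."""
        s = np.zeros(n_patients)
        c = np.zeros(n_patients)
        for idx, r in zip(self.fold_test_indices, self.fold_risks):
            s[idx] += r
            c[idx] += 1
        with np.errstate(invalid="ignore"):
            return np.where(c > 0, s / np.maximum(c, 1), np.nan)


def _expand_grid(grid: dict) -> tuple[list[tuple[float, int]], dict]:
    """Split the grid into (learning_rate, depth) combos and stage candidates."""
    stages = sorted(grid.get("n_stages", [50]))
    combos = list(itertools.product(grid.get("learning_rate", [0.1]),
                                    grid.get("max_depth", [2])))
    return combos, {"stages": stages}


def _fit_model(family: str, params: dict, seed: int):
    if family == "cox":
        return BoostedCoxModel(seed=seed, **params)
    return BoostedClassifierModel(seed=seed, **params)


def _strat_vector(family: str, outcomes) -> np.ndarray:
    if family == "cox":
        return np.asarray(outcomes["event"], int)
    return np.asarray(outcomes, int)


def _fit_and_stage_scores(family, lr, depth, max_stage, X_tr, out_tr, X_te, seed):
    params = {"n_stages": max_stage, "learning_rate": lr, "max_depth": depth}
    model = _fit_model(family, params, seed)
    if family == "cox":
        model.fit(X_tr, out_tr["time"], out_tr["event"])
        staged = model.staged_predict(X_te)
    else:
        model.fit(X_tr, out_tr)
        staged = model.staged_scores(X_te)
    return list(staged)


def _metric(family, scores, out_te):
    if family == "cox":
        return concordance_index(scores, out_te["time"], out_te["event"])
    return roc_auc(scores, out_te)


def _subset_out(family, outcomes, idx):
    if family == "cox":
        return {
            "time": np.asarray(outcomes["time"], float)[idx],
            "event": np.asarray(outcomes["event"], int)[idx],
        }
    return np.asarray(outcomes, int)[idx]


def _tune(family, X, outcomes, spec, combos, stages, rng) -> dict:
    """Inner repeated-CV selection of (learning_rate, depth, n_stages)."""
    strat = _strat_vector(family, outcomes)
    if len(np.unique(strat)) < 2 or min(np.bincount(strat)) < spec.inner_folds:
        # degenerate inner data: fall back to the middle of the grid
        lr, depth = combos[0]
        return {"n_stages": stages[len(stages) // 2], "learning_rate": lr, "max_depth": depth}
    sums = np.zeros((len(combos), len(stages)))
    counts = np.zeros((len(combos), len(stages)))
    max_stage = stages[-1]
    for rep in range(spec.inner_reps):
        skf = StratifiedKFold(
            n_splits=spec.inner_folds, shuffle=True,
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        for tr, te in skf.split(X, strat):
            out_tr = _subset_out(family, outcomes, tr)
            out_te = _subset_out(family, outcomes, te)
            ev_tr = _strat_vector(family, out_tr)
            ev_te = _strat_vector(family, out_te)
            if len(np.unique(ev_tr)) < 2 and family != "cox":
                continue
            if family == "cox" and out_tr["event"].sum() < 2:
                continue
            for ci, (lr, depth) in enumerate(combos):
                try:
                    staged = _fit_and_stage_scores(
                        family, lr, depth, max_stage, X[tr], out_tr, X[te],
                        seed=int(rng.integers(2 ** 31 - 1)),
                    )
                except ValueError:
                    continue
                for si, st in enumerate(stages):
                    try:
                        sums[ci, si] += _metric(family, staged[st - 1], out_te)
                        counts[ci, si] += 1
                    except ValueError:
                        continue
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    ci, si = np.unravel_index(np.argmax(means), means.shape)
    lr, depth = combos[ci]
    return {"n_stages": stages[si], "learning_rate": lr, "max_depth": depth}


def nested_evaluate(
    table: pd.DataFrame,
    outcomes,
    model_family: str,
    spec: ResamplingSpec,
    columns: list[str] | None = None,
    selector=None,
    param_grid: dict | None = None,
    model_name: str = "model",
) -> ResamplingResult:
    """Nested-resampling performance estimate of one model family.

    Parameters
    ----------
    table : feature table (rows = patients).
    outcomes : ``{"time", "event"}`` mapping for ``model_family="cox"``,
        binary labels for ``"classifier"``.
    columns : fixed feature subset (default: all columns).
    selector : optional callable ``selector(train_table, train_outcomes) ->
        list[str]`` run inside each outer training set (leak-free feature
        selection); overrides ``columns``.
    param_grid : boosted-model grid; stage counts are tuned via staged
        predictions of a single fit per (learning rate, depth) combo.
    """
    if model_family not in ("cox", "classifier"):
        raise ValueError("model_family must be 'cox' or 'classifier'")
    grid = param_grid or DEFAULT_PARAM_GRID
    combos, st = _expand_grid(grid)
    stages = st["stages"]
    strat = _strat_vector(model_family, outcomes)
    n = len(table)

    values: list[float] = []
    auprc_vals: list[float] = []
    chosen: list[dict] = []
    fold_idx: list[np.ndarray] = []
    fold_risks: list[np.ndarray] = []
    n_flagged = 0
    X_all = table.to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(table.columns)}

    for rep in range(spec.outer_reps):
        # fold structure depends only on (seed, rep): models evaluated under
        # the same spec see identical splits (paired comparison)
        skf = StratifiedKFold(
            n_splits=spec.outer_folds, shuffle=True,
            random_state=(spec.seed * 9973 + rep) % (2 ** 31 - 1),
        )
        for fold_no, (tr, te) in enumerate(skf.split(X_all, strat)):
            rng = np.random.default_rng([spec.seed, rep, fold_no])
            out_tr = _subset_out(model_family, outcomes, tr)
            out_te = _subset_out(model_family, outcomes, te)
            ev_te = _strat_vector(model_family, out_te)
            flag = False
            if model_family == "cox":
                flag = out_tr["event"].sum() < 2 or out_te["event"].sum() < 1
            else:
                flag = len(np.unique(_strat_vector(model_family, out_tr))) < 2 \
                    or len(np.unique(ev_te)) < 2
            if flag:
                n_flagged += 1
                continue
            if selector is not None:
                cols = selector(table.iloc[tr], out_tr)
            else:
                cols = columns if columns is not None else list(table.columns)
            if len(cols) == 0:
                # empty signature: constant risk, tie-convention metric
                risks = np.zeros(len(te))
                try:
                    values.append(_metric(model_family, risks, out_te))
                    if model_family == "classifier":
                        auprc_vals.append(pr_auprc(risks, out_te))
                except ValueError:
                    n_flagged += 1
                    continue
                chosen.append({})
                fold_idx.append(te)
                fold_risks.append(risks)
                continue
            sel = [col_index[c] for c in cols]
            X = X_all[:, sel]
            params = _tune(model_family, X[tr], out_tr, spec, combos, stages, rng)
            model = _fit_model(model_family, params, seed=int(rng.integers(2 ** 31 - 1)))
            if model_family == "cox":
                model.fit(X[tr], out_tr["time"], out_tr["event"])
                risks = model.predict(X[te])
            else:
                model.fit(X[tr], out_tr)
                risks = model.predict_score(X[te])
            try:
                values.append(_metric(model_family, risks, out_te))
            except ValueError:
                n_flagged += 1
                continue
            if model_family == "classifier":
                auprc_vals.append(pr_auprc(risks, out_te))
            chosen.append(params)
            fold_idx.append(te)
            fold_risks.append(risks)

    extra = {"auprc": np.asarray(auprc_vals)} if model_family == "classifier" else {}
    return ResamplingResult(
        model_name=model_name,
        metric_name="ci" if model_family == "cox" else "auc",
        spec=spec,
        values=np.asarray(values),
        n_flagged=n_flagged,
        chosen_params=chosen,
        extra_metrics=extra,
        fold_test_indices=fold_idx,
        fold_risks=fold_risks,
    )


def evaluate_three_models(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: list[str] | None,
    outcomes,
    model_family: str,
    spec: ResamplingSpec,
    selector=None,
    param_grid: dict | None = None,
) -> dict[str, ResamplingResult]:
    """Clinical vs. radiomic vs. combined model under identical folds.

    The clinical model uses exactly the five clinical covariates; the
    radiomic model uses the selected signature (or the per-fold ``selector``);
    the combined model uses both.  All three share the fold structure through
    the common spec seed, giving paired comparisons.
    """
    both = pd.concat([clinical, features], axis=1)
    clin_cols = list(clinical.columns)

    if selector is not None:
        # radiomic and combined models share the outer folds (same spec
        # seed), so cache per-fold selections by the train row set
        cache: dict = {}
        inner_selector = selector

        def selector(train_table, train_out):
            key = tuple(train_table.index)
            if key not in cache:
                cache[key] = inner_selector(train_table, train_out)
            return cache[key]

    def combined_selector(train_table, train_out):
        return clin_cols + selector(train_table[features.columns], train_out)

    out = {}
    out["clinical"] = nested_evaluate(
        both, outcomes, model_family, spec, columns=clin_cols,
        param_grid=param_grid, model_name="clinical",
    )
    out["radiomic"] = nested_evaluate(
        both, outcomes, model_family, spec,
        columns=None if selector else list(signature),
        selector=(lambda t, o: selector(t[features.columns], o)) if selector else None,
        param_grid=param_grid, model_name="radiomic",
    )
    out["combined"] = nested_evaluate(
        both, outcomes, model_family, spec,
        columns=None if selector else clin_cols + list(signature),
        selector=combined_selector if selector else None,
        param_grid=param_grid, model_name="combined",
    )
    return out


def compare_models(results: dict[str, ResamplingResult]) -> pd.DataFrame:
    """Mean/SD/count summary of the outer-loop metric distributions."""
    rows = []
    for name, res in results.items():
        row = {
            "model": name,
            "metric": res.metric_name,
            "mean": res.mean,
            "sd": res.sd,
            "n_collected": len(res.values),
            "n_flagged": res.n_flagged,
        }
        for extra_name, vals in res.extra_metrics.items():
            row[f"mean_{extra_name}"] = float(np.mean(vals)) if len(vals) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
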