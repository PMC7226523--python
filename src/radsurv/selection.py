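"""Three-step feature selection under subsample stabilization.

The pipeline per resample: (1) univariate screen — single-covariate Cox
(survival endpoint) or one-way ANOVA (recurrence endpoint) with
Benjamini-Hochberg FDR adjustment; (2) recursive correlation pruning of
redundant features; (3) sequential floating forward selection (SFFS) driven
by a cross-validated objective.  Many resamples of 2/3 of the patients are
drawn without replacement, the three steps run on each, and per-feature
selection frequencies are aggregated into a final signature.

Normalization note: ``resampled_selection`` z-scores features over the whole
dataset when ``replication_mode=True`` (mirroring a whole-dataset
normalization workflow, a deliberate and labelled information leak);
the default normalizes inside each resample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._cox import concordance_many, cox_newton, univariate_cox_many
from .survival import concordance_index
from .recurrence import roc_auc


# ---------------------------------------------------------------------------
# univariate screens
# ---------------------------------------------------------------------------

@dataclass
class UnivariateResult:
    feature: str
    statistic: float       # univariate CI (survival) or F statistic (recurrence)
    coefficient: float
    raw_p: float
    fdr_p: float = float("nan")
    failed: bool = False


def univariate_cox(values, times, events, name: str = "") -> UnivariateResult:
    """Single-covariate Cox fit: Wald p-value and univariate concordance.

    The reported statistic is the Harrell concordance of the fitted linear
    predictor (``beta * x``).  Constant features are flagged as failed and
    excluded from downstream steps.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0 or not np.all(np.isfinite(x)):
        return UnivariateResult(name, float("nan"), 0.0, float("nan"), failed=True)
    if np.asarray(events).sum() < 2:
        raise ValueError("need at least 2 events")
    xs = (x - x.mean()) / x.std()
    beta, se, _ = cox_newton(xs[:, None], np.asarray(times, float), np.asarray(events, int))
    z = beta[0] / se[0] if se[0] > 0 else np.inf * np.sign(beta[0])
    p = float(2.0 * stats.norm.sf(abs(z)))
    try:
        ci = concordance_index(beta[0] * xs, times, events)
    except ValueError:
        ci = float("nan")
    return UnivariateResult(name, ci, float(beta[0]), p)


def univariate_anova(values, labels, name: str = "") -> UnivariateResult:
    """One-way ANOVA F test of a feature across outcome classes."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if np.ptp(x) == 0 or not np.all(np.isfinite(x)):
        return UnivariateResult(name, float("nan"), 0.0, float("nan"), failed=True)
    groups = [x[y == g] for g in np.unique(y)]
    if len(groups) < 2:
        return UnivariateResult(name, float("nan"), 0.0, float("nan"), failed=True)
    f, p = stats.f_oneway(*groups)
    return UnivariateResult(name, float(f), float(f), float(p))


def fdr_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(k) = min over j >= k of p_(j) * m / j (clipped at 1), returned in
    the input order; NaNs pass through untouched.
    """
    p = np.asarray(raw_p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def screen_features(
    table: pd.DataFrame, outcomes, endpoint: str = "survival", compute_ci: bool = True
) -> pd.DataFrame:
    """Univariate screen of every column at once; returns a tidy frame with
    columns feature/statistic/coefficient/raw_p/failed/fdr_p.

    Vectorized across features (one damped-Newton pass fits all
    single-covariate Cox models simultaneously); equivalent to calling
    :func:`univariate_cox` / :func:`univariate_anova` per column.
    ``compute_ci=False`` skips the pairwise univariate concordance (the
    screening gate itself only needs the p-values).
    """
    X = table.to_numpy(dtype=float)
    failed = ~np.all(np.isfinite(X), axis=0) | (np.ptp(X, axis=0) == 0)
    Xz = X.copy()
    Xz[:, failed] = 0.0
    mu = Xz.mean(axis=0)
    sd = Xz.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (Xz - mu) / sd

    if endpoint == "survival":
        times = np.asarray(outcomes["time"], float)
        events = np.asarray(outcomes["event"], int)
        beta, se = univariate_cox_many(Xz, times, events)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        raw_p = 2.0 * stats.norm.sf(np.abs(z))
        if compute_ci:
            statistic = concordance_many(Xz * beta[None, :], times, events)
        else:
            statistic = np.full(len(beta), np.nan)
        coef = beta
    else:
        labels = np.asarray(outcomes, int)
        groups = [X[labels == g] for g in np.unique(labels)]
        f, raw_p = stats.f_oneway(*groups)
        statistic = np.asarray(f, dtype=float)
        coef = statistic
    raw_p = np.asarray(raw_p, dtype=float)
    raw_p[failed] = np.nan
    statistic = np.asarray(statistic, dtype=float)
    statistic[failed] = np.nan
    df = pd.DataFrame(
        {
            "feature": list(table.columns),
            "statistic": statistic,
            "coefficient": coef,
            "raw_p": raw_p,
            "failed": failed,
        }
    )
    df["fdr_p"] = fdr_adjust(df["raw_p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------

def correlation_prune(
    table: pd.DataFrame, scores: dict[str, float], threshold: float = 0.8
) -> list[str]:
    """Recursively drop the weaker member of any feature pair with
    ``|Pearson r| > threshold``.

    ``scores`` maps feature name to univariate strength (higher = stronger);
    ties break on feature name order, so the result is deterministic.
    Mutually-uncorrelated features are never removed.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    corr = np.abs(np.corrcoef(table.to_numpy(), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = dict.fromkeys(cols, True)
    idx = {c: i for i, c in enumerate(cols)}

    def weaker(a: str, b: str) -> str:
        sa, sb = scores.get(a, -np.inf), scores.get(b, -np.inf)
        if sa == sb:
            return max(a, b)  # later name drops
        return a if sa < sb else b

    changed = True
    while changed:
        changed = False
        live = [c for c in cols if alive[c]]
        for i, a in enumerate(live):
            for b in live[i + 1:]:
                if alive[a] and alive[b] and corr[idx[a], idx[b]] > threshold:
                    alive[weaker(a, b)] = False
                    changed = True
    return [c for c in cols if alive[c]]


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------

def sffs(candidates: list[str], objective, max_size: int) -> list[str]:
    """Sequential floating forward selection.

    Forward: add the feature maximizing the objective.  Floating: while
    removing some feature strictly improves on the best objective recorded at
    the smaller size, remove it.  ``objective(subset) -> float`` is maximized;
    failures score -inf.  Returns the best subset found (any size up to
    ``max_size``).
    """
    def safe_obj(subset):
        try:
            v = objective(list(subset))
            return v if np.isfinite(v) else -np.inf
        except Exception:
            return -np.inf

    best_at_size: dict[int, tuple[float, list[str]]] = {0: (-np.inf, [])}
    current: list[str] = []
    current_score = -np.inf
    while len(current) < max_size:
        remaining = [c for c in candidates if c not in current]
        if not remaining:
            break
        scored = [(safe_obj(current + [c]), c) for c in remaining]
        add_score, add_feat = max(scored, key=lambda t: (t[0], t[1]))
        current = current + [add_feat]
        current_score = add_score
        k = len(current)
        if add_score > best_at_size.get(k, (-np.inf, []))[0]:
            best_at_size[k] = (add_score, list(current))
        # floating exclusion
        while len(current) > 2:
            k = len(current)
            drop_scored = [
                (safe_obj([f for f in current if f != d]), d) for d in current
            ]
            drop_score, drop_feat = max(drop_scored, key=lambda t: (t[0], t[1]))
            if drop_score > best_at_size.get(k - 1, (-np.inf, []))[0]:
                current = [f for f in current if f != drop_feat]
                current_score = drop_score
                best_at_size[k - 1] = (drop_score, list(current))
            else:
                break
    if not best_at_size:
        return []
    best_score, best_subset = max(
        best_at_size.values(), key=lambda t: (t[0], -len(t[1]))
    )
    return best_subset if np.isfinite(best_score) else []


# ---------------------------------------------------------------------------
# cross-validated objectives
# ---------------------------------------------------------------------------

def make_cv_objective(
    table: pd.DataFrame,
    outcomes,
    endpoint: str = "survival",
    n_folds: int = 3,
    seed: int = 0,
):
    """3-fold CV objective for SFFS: mean test CI of a linear Cox model
    (survival) or mean test AUC of a logistic model (recurrence).

    Linear models keep SFFS tractable (hundreds of subset evaluations per
    resample); a boosted objective can be swapped in via
    :func:`resampled_selection`'s ``objective_factory``.
    """
    if endpoint == "survival":
        times = np.asarray(outcomes["time"], float)
        events = np.asarray(outcomes["event"], int)
        strat = events
    else:
        labels = np.asarray(outcomes, int)
        strat = labels

    def fold_values(subset: list[str]) -> list[float]:
        if not subset:
            return []
        X = table[subset].to_numpy(dtype=float)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        vals = []
        for tr, te in skf.split(X, strat):
            if endpoint == "survival":
                if events[tr].sum() < 2 or events[te].sum() < 1:
                    continue
                beta, _, _ = cox_newton(X[tr], times[tr], events[tr], ridge=1e-4)
                try:
                    vals.append(concordance_index(X[te] @ beta, times[te], events[te]))
                except ValueError:
                    continue
            else:
                if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
                    continue
                clf = LogisticRegression(max_iter=200, C=1.0)
                clf.fit(X[tr], labels[tr])
                vals.append(roc_auc(clf.decision_function(X[te]), labels[te]))
        return vals

    def objective(subset: list[str]) -> float:
        vals = fold_values(subset)
        return float(np.mean(vals)) if vals else -np.inf

    objective.fold_values = fold_values
    return objective


# ---------------------------------------------------------------------------
# resampled selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionSpec:
    """Resampling and threshold knobs of the 3-step selection."""

    n_resamples: int = 1000
    subsample_fraction: float = 2.0 / 3.0
    fdr_threshold: float = 0.25
    correlation_threshold: float = 0.8
    max_candidates: int = 30      # cap passed to SFFS, strongest-first
    max_signature_size: int = 8
    cv_folds: int = 3
    seed: int = 0
    replication_mode: bool = False  # z-score on the whole dataset (labelled leak)


@dataclass
class SelectionReport:
    spec: SelectionSpec
    endpoint: str
    per_resample: list[list[str]]
    selection_frequency: pd.Series
    final_signature: list[str]
    signature_size_scores: dict[int, float] = field(default_factory=dict)
    screen: pd.DataFrame | None = None

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "endpoint": self.endpoint,
            "n_resamples": self.spec.n_resamples,
            "subsample_fraction": self.spec.subsample_fraction,
            "seed": self.spec.seed,
            "final_signature": self.final_signature,
            "selection_frequency": self.selection_frequency.to_dict(),
            "signature_size_scores": {str(k): v for k, v in self.signature_size_scores.items()},
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    def to_csv(self, path: str | Path) -> None:
        """Table mirroring the selected-feature report layout: feature,
        class, selection frequency, univariate statistic and FDR p."""
        rows = []
        for feat in self.selection_frequency.index:
            parts = feat.split("_")
            cls = parts[2] if parts and parts[0] == "wavelet" and len(parts) > 2 \
                else (parts[1] if len(parts) > 1 else "")
            row = {
                "feature": feat,
                "feature_class": cls,
                "selection_frequency": self.selection_frequency[feat],
                "in_signature": feat in self.final_signature,
            }
            if self.screen is not None and feat in set(self.screen["feature"]):
                sub = self.screen[self.screen["feature"] == feat].iloc[0]
                row["statistic"] = sub["statistic"]
                row["fdr_p"] = sub["fdr_p"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0).replace(0.0, 1.0)
    return (df - df.mean()) / sd


def resampled_selection(
    table: pd.DataFrame,
    outcomes,
    spec: SelectionSpec | None = None,
    endpoint: str = "survival",
    objective_factory=None,
) -> SelectionReport:
    """Run the 3-step selection under 2/3 subsample stabilization.

    Per resample: draw ``subsample_fraction`` of the patients without
    replacement, screen univariately (keep FDR < threshold, strongest
    ``max_candidates``), prune correlated features, run SFFS with a
    cross-validated objective.  Selection frequencies aggregate over
    resamples; the final signature is the smallest top-k-by-frequency set
    whose full-data refit objective is within one standard error of the best
    k (one-SE rule).

    ``objective_factory(table, outcomes, endpoint, seed)`` may override the
    default linear CV objective.
    """
    spec = spec or SelectionSpec()
    rng = np.random.default_rng(spec.seed)
    n = len(table)
    if endpoint == "survival":
        times = np.asarray(outcomes["time"], float)
        events = np.asarray(outcomes["event"], int)
    else:
        labels = np.asarray(outcomes, int)
    if spec.replication_mode:
        table = _zscore(table)

    factory = objective_factory or make_cv_objective
    m = max(2, int(round(spec.subsample_fraction * n)))
    per_resample: list[list[str]] = []
    counts = pd.Series(0.0, index=table.columns)
    for rep in range(spec.n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        sub = table.iloc[idx]
        if not spec.replication_mode:
            sub = _zscore(sub)
        if endpoint == "survival":
            out_sub = {"time": times[idx], "event": events[idx]}
            if out_sub["event"].sum() < 2:
                per_resample.append([])
                continue
        else:
            out_sub = labels[idx]
            if len(np.unique(out_sub)) < 2:
                per_resample.append([])
                continue
        screen = screen_features(sub, out_sub, endpoint, compute_ci=False)
        passed = screen[(~screen["failed"]) & (screen["fdr_p"] < spec.fdr_threshold)]
        if passed.empty:
            per_resample.append([])
            continue
        passed = passed.sort_values(["raw_p", "feature"]).head(spec.max_candidates * 2)
        # univariate strength for pruning: smaller p = stronger (monotone in
        # |Wald z| for survival, in F for recurrence)
        scores = {
            r.feature: -np.log10(max(r.raw_p, 1e-300)) for r in passed.itertuples()
        }
        pruned = correlation_prune(sub[passed["feature"].tolist()],
                                   scores, spec.correlation_threshold)
        pruned = sorted(pruned, key=lambda f: (-scores[f], f))[: spec.max_candidates]
        if not pruned:
            per_resample.append([])
            continue
        objective = factory(sub, out_sub, endpoint, seed=spec.seed + rep)
        chosen = sffs(pruned, objective, spec.max_signature_size)
        per_resample.append(chosen)
        for f in chosen:
            counts[f] += 1

    freq = counts / spec.n_resamples
    freq = freq.sort_values(ascending=False, kind="stable")

    # final signature: one-SE rule on a repeated-CV refit objective (several
    # CV repetitions stabilize both the mean and its standard error)
    norm_full = _zscore(table)
    out_full = {"time": times, "event": events} if endpoint == "survival" else labels
    n_cv_repeats = 4
    objectives = [
        factory(norm_full, out_full, endpoint, seed=spec.seed + 7919 * r)
        for r in range(n_cv_repeats)
    ]

    def refit_folds(subset):
        vals = []
        for obj in objectives:
            if hasattr(obj, "fold_values"):
                vals.extend(obj.fold_values(subset))
            else:
                vals.append(obj(subset))
        return vals

    ranked = [f for f in freq.index if freq[f] > 0]
    size_scores: dict[int, float] = {}
    k_max = min(spec.max_signature_size, len(ranked))
    best_sig: list[str] = []
    if k_max > 0:
        size_folds = {k: refit_folds(ranked[:k]) for k in range(1, k_max + 1)}
        size_scores = {
            k: float(np.mean(v)) if v else -np.inf for k, v in size_folds.items()
        }
        finite = {k: v for k, v in size_scores.items() if np.isfinite(v)}
        if finite:
            best_k = max(finite, key=lambda k: (finite[k], -k))
            best_score = finite[best_k]
            folds = size_folds[best_k]
            se = float(np.std(folds, ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else 0.0
            eligible = [k for k, v in finite.items() if v >= best_score - se]
            best_sig = ranked[: min(eligible)]
    screen_full = screen_features(norm_full, out_full, endpoint)
    if not best_sig and ranked:
        best_sig = ranked[:1]
    return SelectionReport(
        spec=spec,
        endpoint=endpoint,
        per_resample=per_resample,
        selection_frequency=freq,
        final_signature=best_sig,
        signature_size_scores=size_scores,
        screen=screen_full,
    )
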