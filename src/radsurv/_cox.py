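"""Cox partial-likelihood internals (Efron tie handling).

Hand-vectorized because the univariate screen evaluates the full 841-feature
panel across hundreds of resamples and the boosted ensemble needs the
per-sample gradient at every stage; cross-checked against lifelines in the
test suite.
"""

from __future__ import annotations

import numpy as np


def _sorted_groups(times: np.ndarray, events: np.ndarray):
    """Sort by time ascending (events before censorings at ties) and locate
    tied event groups.  Returns order, and per-group (start of risk set,
    member indices of the event group) in sorted coordinates."""
    order = np.lexsort((1 - events, times))
    t = times[order]
    e = events[order]
    groups = []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k] == 1]
        if d_idx:
            groups.append((i, np.asarray(d_idx)))
        i = j
    return order, t, e, groups


class EfronData:
    """Precomputed sort/tie structure for fast repeated Efron evaluations.

    Flattens the (group, within-group-rank) double loop into arrays so the
    partial log-likelihood and its per-sample gradient are pure numpy ops —
    the boosted ensemble evaluates both at every stage.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=np.float64)
        events = np.asarray(events, dtype=np.int64)
        self.n = len(times)
        self.order, _, self.e_sorted, groups = _sorted_groups(times, events)
        self.inv_order = np.empty(self.n, dtype=np.int64)
        self.inv_order[self.order] = np.arange(self.n)
        self.starts = np.array([g[0] for g in groups], dtype=np.int64)
        self.n_groups = len(groups)
        member_idx = []
        member_group = []
        pair_group = []
        pair_frac = []
        for gi, (start, d_idx) in enumerate(groups):
            d = len(d_idx)
            member_idx.extend(d_idx.tolist())
            member_group.extend([gi] * d)
            pair_group.extend([gi] * d)
            pair_frac.extend((np.arange(d) / d).tolist())
        self.member_idx = np.asarray(member_idx, dtype=np.int64)
        self.member_group = np.asarray(member_group, dtype=np.int64)
        self.pair_group = np.asarray(pair_group, dtype=np.int64)
        self.pair_frac = np.asarray(pair_frac, dtype=np.float64)

    def _denominators(self, w: np.ndarray):
        suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        s_r = suffix[self.starts]
        s_d = np.bincount(self.member_group, weights=w[self.member_idx],
                          minlength=self.n_groups)
        z0 = s_r[self.pair_group] - self.pair_frac * s_d[self.pair_group]
        return z0

    def loglik(self, f: np.ndarray) -> float:
        fs = f[self.order]
        fs = fs - fs.max()  # common shift cancels in the partial likelihood
        w = np.exp(fs)
        z0 = self._denominators(w)
        return float(fs[self.member_idx].sum() - np.log(z0).sum())

    def gradient(self, f: np.ndarray) -> np.ndarray:
        fs = f[self.order]
        w = np.exp(fs - fs.max())
        z0 = self._denominators(w)
        inv = 1.0 / z0
        a_g = np.bincount(self.pair_group, weights=inv, minlength=self.n_groups)
        c_g = np.bincount(self.pair_group, weights=self.pair_frac * inv,
                          minlength=self.n_groups)
        adds = np.zeros(self.n)
        np.add.at(adds, self.starts, a_g)
        cum_a = np.cumsum(adds)
        grad = self.e_sorted - w * cum_a
        grad[self.member_idx] += w[self.member_idx] * c_g[self.member_group]
        return grad[self.inv_order]


def cox_loglik_f(times: np.ndarray, events: np.ndarray, f: np.ndarray) -> float:
    """Efron partial log-likelihood of per-sample linear predictors ``f``."""
    return EfronData(times, events).loglik(np.asarray(f, dtype=np.float64))


def cox_gradient_f(times: np.ndarray, events: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Gradient of the Efron partial log-likelihood w.r.t. ``f`` (per sample)."""
    return EfronData(times, events).gradient(np.asarray(f, dtype=np.float64))


def univariate_cox_many(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
    ridge: float = 1e-9,
):
    """Fit all single-covariate Cox models of the columns of ``X`` at once.

    Damped Newton (steps clipped to +-1 per iteration) on the Efron partial
    likelihood, vectorized across features.  Columns should be standardized.
    Returns ``(beta, se)`` arrays of length ``X.shape[1]``.
    """
    X = np.asarray(X, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    order, _, _, groups = _sorted_groups(times, events)
    Xs = X[order]
    n, p = Xs.shape
    sum_xd = np.zeros(p)
    for _, d_idx in groups:
        sum_xd += Xs[d_idx].sum(axis=0)

    beta = np.zeros(p)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = Xs * beta
        eta = eta - eta.max(axis=0)
        w = np.exp(eta)
        wx = w * Xs
        wxx = wx * Xs
        s0 = np.vstack([np.cumsum(w[::-1], axis=0)[::-1], np.zeros(p)])
        s1 = np.vstack([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros(p)])
        s2 = np.vstack([np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros(p)])
        g = sum_xd.copy()
        info = np.zeros(p)
        for start, d_idx in groups:
            d = len(d_idx)
            fr = (np.arange(d) / d)[:, None]
            z0 = s0[start][None, :] - fr * w[d_idx].sum(axis=0)[None, :]
            z1 = s1[start][None, :] - fr * wx[d_idx].sum(axis=0)[None, :]
            z2 = s2[start][None, :] - fr * wxx[d_idx].sum(axis=0)[None, :]
            g -= (z1 / z0).sum(axis=0)
            info += (z2 / z0 - (z1 / z0) ** 2).sum(axis=0)
        info = info + ridge
        step = np.clip(g / info, -1.0, 1.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(info)
    return beta, se


def concordance_many(R: np.ndarray, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Harrell concordance of every column of risk matrix ``R`` at once.

    Same comparability rule as :func:`radsurv.survival.concordance_index`.
    Returns NaN-filled output when no comparable pair exists.
    """
    R = np.asarray(R, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=np.int64)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    comp = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    np.fill_diagonal(comp, False)
    ii, jj = np.nonzero(comp)
    if ii.size == 0:
        return np.full(R.shape[1], np.nan)
    a = R[ii, :]
    b = R[jj, :]
    score = np.where(a > b, 1.0, np.where(a == b, 0.5, 0.0))
    return score.mean(axis=0)


def cox_newton(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-8,
    ridge: float = 1e-9,
):
    """Multivariate Cox fit by Newton-Raphson with step halving.

    Returns ``(beta, se, loglik)``.  ``ridge`` adds a tiny quadratic penalty
    for numerical stability on nearly-separable inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if events.sum() < 2:
        raise ValueError("need at least 2 events")

    ef = EfronData(times, events)
    Xs = X[ef.order]
    members = ef.member_idx
    pg = ef.pair_group
    frac = ef.pair_frac
    sum_xd = Xs[members].sum(axis=0)

    def negll_grad_hess(beta):
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        wx = w[:, None] * Xs
        wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
        s0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])[ef.starts]
        s1 = np.vstack([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros((1, p))])[ef.starts]
        s2 = np.concatenate(
            [np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros((1, p, p))]
        )[ef.starts]
        g_count = ef.n_groups
        s0d = np.bincount(ef.member_group, weights=w[members], minlength=g_count)
        s1d = np.zeros((g_count, p))
        np.add.at(s1d, ef.member_group, wx[members])
        s2d = np.zeros((g_count, p, p))
        np.add.at(s2d, ef.member_group, wxx[members])
        z0 = s0[pg] - frac * s0d[pg]
        z1 = s1[pg] - frac[:, None] * s1d[pg]
        z2 = s2[pg] - frac[:, None, None] * s2d[pg]
        ll = (eta[members] - shift).sum() - np.log(z0).sum()
        g = sum_xd - (z1 / z0[:, None]).sum(axis=0)
        zn = z1 / z0[:, None]
        h = -(z2 / z0[:, None, None]).sum(axis=0) + np.einsum("li,lj->ij", zn, zn)
        return -ll + 0.5 * ridge * beta @ beta, -(g - ridge * beta), -(h - ridge * np.eye(p))

    beta = np.zeros(p)
    nll, grad, hess = negll_grad_hess(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # backtracking: hess is the negative-loglik Hessian (PSD), descend -step
        t_step = 1.0
        for _ in range(30):
            cand = beta - t_step * step
            nll_new, grad_new, hess_new = negll_grad_hess(cand)
            if nll_new <= nll + 1e-12:
                break
            t_step *= 0.5
        else:
            break
        moved = np.max(np.abs(cand - beta))
        beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
        if moved < tol or np.max(np.abs(grad)) < tol:
            break
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, se, -nll
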