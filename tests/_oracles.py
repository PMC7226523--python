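"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles with explicit Python loops,
deliberately ignoring the vectorized implementations under test.
"""

from __future__ import annotations

import itertools

import numpy as np

DIRECTIONS_13 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
]
NEIGHBORS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def trilinear(data: np.ndarray, spacing, origin, point) -> float:
    """Direct trilinear interpolation at a physical point (voxel centers at
    origin + index * spacing)."""
    idx = [(p - o) / s for p, o, s in zip(point, origin, spacing)]
    base = [int(np.floor(v)) for v in idx]
    frac = [v - b for v, b in zip(idx, base)]
    val = 0.0
    for dx, dy, dz in itertools.product((0, 1), repeat=3):
        wx = frac[0] if dx else 1 - frac[0]
        wy = frac[1] if dy else 1 - frac[1]
        wz = frac[2] if dz else 1 - frac[2]
        i = min(max(base[0] + dx, 0), data.shape[0] - 1)
        j = min(max(base[1] + dy, 0), data.shape[1] - 1)
        k = min(max(base[2] + dz, 0), data.shape[2] - 1)
        val += wx * wy * wz * data[i, j, k]
    return val


def conv3d_periodic_separable(x: np.ndarray, kernels) -> np.ndarray:
    """out[i] = sum_j w[j] * x[(i - j + m//2) mod n] applied per axis."""
    out = x.astype(float).copy()
    for axis, w in enumerate(kernels):
        m = len(w)
        src = np.moveaxis(out, axis, 0)
        res = np.zeros_like(src)
        n = src.shape[0]
        for i in range(n):
            acc = np.zeros(src.shape[1:])
            for j in range(m):
                acc += w[j] * src[(i - j + m // 2) % n]
            res[i] = acc
        out = np.moveaxis(res, 0, axis)
    return out


def glcm_counts(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Symmetrized co-occurrence counts for one direction."""
    mat = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                xx, yy, zz = x + direction[0], y + direction[1], z + direction[2]
                if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                    continue
                b = levels[xx, yy, zz]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def glrlm_counts(levels: np.ndarray, direction, n_levels: int) -> dict:
    """Maximal-run counts {(level, length): count} for one direction."""
    runs: dict = {}
    nx, ny, nz = levels.shape

    def inside(p):
        return 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0:
                    continue
                prev = (x - direction[0], y - direction[1], z - direction[2])
                if inside(prev) and levels[prev] == g:
                    continue  # not a run start
                length = 1
                cur = (x + direction[0], y + direction[1], z + direction[2])
                while inside(cur) and levels[cur] == g:
                    length += 1
                    cur = (cur[0] + direction[0], cur[1] + direction[1], cur[2] + direction[2])
                runs[(g, length)] = runs.get((g, length), 0) + 1
    return runs


def glszm_zones(levels: np.ndarray, n_levels: int) -> dict:
    """26-connected zone sizes {(level, size): count} by flood fill."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones: dict = {}
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0 or visited[x, y, z]:
                    continue
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        p = (cx + dx, cy + dy, cz + dz)
                        if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                                and not visited[p] and levels[p] == g):
                            visited[p] = True
                            stack.append(p)
                zones[(g, size)] = zones.get((g, size), 0) + 1
    return zones


def gldm_counts(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict:
    """Dependence counts {(level, 1 + n_dependent_neighbors): count}."""
    out: dict = {}
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0:
                    continue
                dep = 0
                for dx, dy, dz in NEIGHBORS_26:
                    p = (x + dx, y + dy, z + dz)
                    if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                            and levels[p] > 0 and abs(int(levels[p]) - int(g)) <= alpha):
                        dep += 1
                key = (g, dep + 1)
                out[key] = out.get(key, 0) + 1
    return out


def ngtdm_s_n(levels: np.ndarray, n_levels: int):
    """(s_i, n_i) arrays: per-level sums of |level - mean masked neighbor|."""
    nx, ny, nz = levels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0:
                    continue
                vals = []
                for dx, dy, dz in NEIGHBORS_26:
                    p = (x + dx, y + dy, z + dz)
                    if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                            and levels[p] > 0):
                        vals.append(levels[p])
                n[g - 1] += 1
                if vals:
                    s[g - 1] += abs(g - float(np.mean(vals)))
    return s, n


def harrell_ci(risks, times, events) -> float:
    """Pairwise concordance: shorter time with event is comparable; events
    tied in time with a censoring are comparable; tied-time double events are
    not.  Risk ties score 0.5."""
    num = 0.0
    den = 0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1.0
            elif risks[i] == risks[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def pairwise_auc(scores, labels) -> float:
    num = 0.0
    den = 0
    for i in range(len(scores)):
        for j in range(len(scores)):
            if labels[i] == 1 and labels[j] == 0:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def bh_adjust(pvals) -> np.ndarray:
    """p_(k) * m / k with a running minimum from the largest rank down."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return np.array(adj)


def anova_f(groups) -> float:
    """One-way fixed-effects F from the classic sums-of-squares table."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def chi2_stat(table) -> tuple[float, int]:
    """Pearson chi-square and dof from expected counts."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, dof


def logrank_2group(times_a, events_a, times_b, events_b) -> float:
    """2-group log-rank chi-square via the observed-minus-expected table."""
    times_a, events_a = np.asarray(times_a, float), np.asarray(events_a, int)
    times_b, events_b = np.asarray(times_b, float), np.asarray(events_b, int)
    all_times = np.unique(np.concatenate([times_a[events_a == 1], times_b[events_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = (times_a >= t).sum()
        n_b = (times_b >= t).sum()
        d_a = ((times_a == t) & (events_a == 1)).sum()
        d_b = ((times_b == t) & (events_b == 1)).sum()
        n = n_a + n_b
        d = d_a + d_b
        if n < 2 or d == 0:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        o_minus_e += d_a - e_a
        var += v
    return o_minus_e ** 2 / var


def cox_score_at_zero(x, times, events) -> float:
    """Partial-likelihood score U(0) = sum_events (x_i - risk-set mean of x)
    for untied survival times."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    u = 0.0
    for i in range(len(x)):
        if events[i] != 1:
            continue
        risk = x[times >= times[i]]
        u += x[i] - risk.mean()
    return u
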