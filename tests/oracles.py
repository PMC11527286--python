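"""Independent brute-force oracles shared by the test suite.

These are deliberately naive implementations — dense sampling, direct loops,
full enumeration — kept free of any code path they are used to check.
"""

from __future__ import annotations

import math

import numpy as np


def sholl_by_dense_sampling(brain, preset, center, samples_per_edge: int = 2048) -> int:
    """Count circle crossings by sampling each edge densely.

    For every edge, the point p(t) is sampled on a uniform grid in t; a
    crossing is an adjacent sample pair on opposite sides of a circle
    (inside = distance <= r).  Independent of the analytic segment-circle
    solution used by the package.
    """
    segs = []
    for trace in brain.traces:
        if trace.neuron_class != preset.target_class:
            continue
        for a, b in trace.edges():
            segs.append(((a.x, a.y), (b.x, b.y)))
    if not segs:
        return 0
    seg = np.asarray(segs)  # (E, 2, 2)
    t = np.linspace(0.0, 1.0, samples_per_edge + 1)
    pts = seg[:, None, 0, :] + t[None, :, None] * (seg[:, 1, :] - seg[:, 0, :])[:, None, :]
    d = np.hypot(pts[..., 0] - center[0], pts[..., 1] - center[1])
    radii = preset.spacing * np.arange(1, preset.n_circles + 1)
    inside = d[:, :, None] <= radii[None, None, :]  # (E, S+1, R)
    crossings = np.logical_xor(inside[:, 1:, :], inside[:, :-1, :])
    return int(crossings.sum())


def qp_direct(x: np.ndarray, period_bins: int) -> float:
    """Sokolove–Bushell Qp evaluated with plain Python loops."""
    x = [float(v) for v in x]
    n = len(x)
    grand = sum(x) / n
    s2 = sum((v - grand) ** 2 for v in x) / n
    cols: dict[int, list[float]] = {}
    for i, v in enumerate(x):
        cols.setdefault(i % period_bins, []).append(v)
    total = 0.0
    for vals in cols.values():
        m_h = sum(vals) / len(vals)
        total += len(vals) * (m_h - grand) ** 2
    return total / s2


def fisher_p_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose point
    probability is <= that of the observed table (with a small relative
    tolerance for float ties, as is conventional).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def prob(a_):
        return math.exp(
            log_comb(r1, a_) + log_comb(r2, c1 - a_) - log_comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for a_ in range(lo, hi + 1):
        p = prob(a_)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def path_length_by_bfs(trace, a: int, b: int) -> float:
    """Geodesic a→b via breadth-first search on the undirected edge list."""
    from collections import deque

    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v in trace.edges():
        d = math.hypot(u.x - v.x, u.y - v.y)
        adj.setdefault(u.node_id, []).append((v.node_id, d))
        adj.setdefault(v.node_id, []).append((u.node_id, d))
    if a == b:
        return 0.0
    dist = {a: 0.0}
    queue = deque([a])
    while queue:
        u = queue.popleft()
        for v, d in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + d
                queue.append(v)
    return dist[b]


def two_way_ss_by_hand(values, fa, fb):
    """Sums-of-squares for a balanced two-factor layout, from the textbook
    decomposition (grand/row/column/cell means)."""
    import itertools

    values = np.asarray(values, dtype=float)
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    grand = values.mean()
    levels_a = sorted(set(fa))
    levels_b = sorted(set(fb))
    ss_a = sum(
        (values[fa == la].mean() - grand) ** 2 * (fa == la).sum()
        for la in levels_a
    )
    ss_b = sum(
        (values[fb == lb].mean() - grand) ** 2 * (fb == lb).sum()
        for lb in levels_b
    )
    ss_cells = 0.0
    ss_err = 0.0
    for la, lb in itertools.product(levels_a, levels_b):
        mask = (fa == la) & (fb == lb)
        cell = values[mask]
        ss_cells += len(cell) * (cell.mean() - grand) ** 2
        ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_err = len(values) - len(levels_a) * len(levels_b)
    f_a = (ss_a / df_a) / (ss_err / df_err)
    f_b = (ss_b / df_b) / (ss_err / df_err)
    f_ab = (ss_ab / df_ab) / (ss_err / df_err)
    return {"A": f_a, "B": f_b, "A:B": f_ab}
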