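"""Independent brute-force oracles used to check the graph-metric code.

Everything here is written from first principles (exhaustive enumeration,
Floyd-Warshall, hand-rolled sums of squares) and deliberately shares no code
with the package implementation it verifies.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering by explicit triangle enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def bf_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by Floyd-Warshall."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_char_path_length(adj: np.ndarray) -> tuple[float, float]:
    d = bf_distances(adj)
    n = adj.shape[0]
    vals, total = [], 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total += 1
            if np.isfinite(d[i, j]):
                vals.append(d[i, j])
    return float(np.mean(vals)), 1.0 - len(vals) / total


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = adj.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


def bf_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = bf_distances(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1)
    return out


def bf_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nb, nb)]
        vals.append(bf_global_efficiency(sub))
    return float(np.mean(vals))


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    n = adj.shape[0]
    d = bf_distances(adj)
    if not np.isfinite(d[s, t]):
        return []
    target_len = int(d[s, t])
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            if len(path) - 1 == target_len:
                paths.append(tuple(path))
            return
        if len(path) - 1 >= target_len:
            return
        for nxt in range(n):
            if adj[last, nxt] and nxt not in path:
                extend(path + [nxt])

    extend([s])
    return paths


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs, by path enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                out[v] += through / sigma
    return out


def bf_trapezoid(values, grid) -> float:
    acc = 0.0
    for i in range(len(grid) - 1):
        acc += 0.5 * (values[i] + values[i + 1]) * (grid[i + 1] - grid[i])
    return acc


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi adjacency as a symmetric boolean matrix without loops."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return adj | adj.T


def oneway_anova_f(groups: list[np.ndarray]) -> float:
    """Textbook one-way ANOVA F from explicit sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form pooled-variance two-sample t (a minus b)."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def bh_stepup(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Hand-computed Benjamini-Hochberg step-up flags and adjusted p."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    flags = np.zeros(m, bool)
    kmax = 0
    for i in range(1, m + 1):
        if ranked[i - 1] <= i * q / m:
            kmax = i
    if kmax:
        flags[order[:kmax]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m, 0, -1):
        running = min(running, ranked[i - 1] * m / i)
        adj[order[i - 1]] = running
    return flags, adj
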