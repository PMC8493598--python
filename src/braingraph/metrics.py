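"""Topological metrics of binary undirected brain graphs.

Global: mean clustering coefficient Cp, characteristic path length Lp,
global efficiency Eg, local efficiency Eloc, and the small-world ratios
gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda against
degree-preserving rewired null graphs. Nodal: degree centrality DC,
betweenness centrality BC (raw unordered-pair convention), nodal efficiency
NE. Each metric is summarized across the sparsity grid by the trapezoidal
area under its metric-versus-sparsity curve (AUC).

Conventions for fragmenting graphs (low sparsity): Lp is the mean hop
distance over *reachable* ordered pairs, with the unreachable fraction
reported alongside; efficiencies use 1/inf = 0 and so remain well defined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .errors import InputError, MetricUndefinedError
from .network import BinaryNetworkStack
from .nulls import NullEnsembleSpec, null_ensemble_means

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eg", "Eloc")
NODAL_METRICS = ("DC", "BC", "NE")


def _check_adj(adj) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InputError("adjacency must be square")
    adj = adj.astype(bool)
    if not np.array_equal(adj, adj.T):
        raise InputError("adjacency must be symmetric (undirected graph)")
    if np.any(np.diag(adj)):
        raise InputError("self-loops are not allowed")
    return adj


def clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering C_i = 2 t_i / (k_i (k_i - 1)); 0 when k_i < 2."""
    adj = _check_adj(adj)
    a = adj.astype(np.float64)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0   # triangles through each node
    k = a.sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c


def mean_clustering(adj: np.ndarray) -> float:
    """Cp: clustering coefficient averaged over all nodes."""
    return float(clustering_coefficients(adj).mean())


def shortest_path_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by breadth-first search; inf when unreachable.

    Implemented as simultaneous BFS from every source via boolean matrix
    powers: after k multiplications the reachability matrix holds all pairs
    at distance <= k, so newly reached pairs get distance k. Equivalent to
    per-source BFS but with no per-call graph-construction overhead, which
    matters when thousands of null graphs are measured.
    """
    adj = _check_adj(adj)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    a = adj.astype(np.float32)
    reach = adj.copy()
    dist[adj] = 1.0
    k = 1
    while k < n:
        new = ((reach @ a) > 0) & ~reach
        np.fill_diagonal(new, False)
        if not new.any():
            break
        k += 1
        dist[new] = k
        reach |= new
    return dist


def characteristic_path_length(dist: np.ndarray) -> tuple[float, float]:
    """(Lp, fraction of unreachable ordered pairs).

    Lp averages the finite off-diagonal distances; an edgeless graph has no
    reachable pair and Lp is undefined.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_pairs = n * (n - 1)
    if not finite.any():
        raise MetricUndefinedError("no reachable pairs: Lp undefined")
    frac_unreachable = 1.0 - finite.sum() / n_pairs
    return float(dist[finite].mean()), float(frac_unreachable)


def nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    """NE_i = mean over j != i of 1/d(i, j), with 1/inf = 0."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(dist: np.ndarray) -> float:
    """Eg = mean over ordered pairs of inverse distance (= mean of NE)."""
    return float(nodal_efficiency(dist).mean())


def global_efficiency_adj(adj: np.ndarray) -> float:
    return global_efficiency(shortest_path_matrix(adj))


def local_efficiency(adj: np.ndarray) -> float:
    """Eloc: mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (the node itself excluded); nodes with fewer
    than two neighbours contribute 0."""
    adj = _check_adj(adj)
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        vals[i] = global_efficiency_adj(sub)
    return float(vals.mean())


def degree_centrality(adj: np.ndarray) -> np.ndarray:
    """DC_i: number of edges incident to node i."""
    return _check_adj(adj).sum(axis=1).astype(int)


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """Raw (unnormalized) betweenness, unordered-pair convention.

    BC_i = sum over unordered pairs {s, t} (s, t != i) of the fraction of
    shortest s-t paths passing through i; unreachable pairs contribute 0.
    Computed with Brandes' algorithm.
    """
    adj = _check_adj(adj)
    g = nx.from_numpy_array(adj.astype(int))
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(adj.shape[0])])


def auc(values, grid) -> float:
    """Trapezoidal area under a metric-versus-sparsity curve."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise InputError(
            f"values ({values.shape}) and grid ({grid.shape}) must align"
        )
    return float(np.trapezoid(values, grid))


def global_metrics_at(adj: np.ndarray) -> dict:
    """Cp, Lp (+ unreachable fraction), Eg, Eloc of one graph."""
    dist = shortest_path_matrix(adj)
    lp, frac = characteristic_path_length(dist)
    return {
        "Cp": mean_clustering(adj),
        "Lp": lp,
        "fraction_unreachable_pairs": frac,
        "Eg": global_efficiency(dist),
        "Eloc": local_efficiency(adj),
    }


def small_world_at(
    adj: np.ndarray, null_spec: NullEnsembleSpec, rng: np.random.Generator
) -> dict:
    """gamma, lambda, sigma of one graph against a rewired null ensemble."""
    cp = mean_clustering(adj)
    lp, _ = characteristic_path_length(shortest_path_matrix(adj))
    cp_rand, lp_rand = null_ensemble_means(adj, null_spec, rng)
    if cp_rand == 0 or lp_rand == 0:
        raise MetricUndefinedError("null ensemble mean Cp or Lp is zero")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return {"gamma": gamma, "lambda": lam, "sigma": gamma / lam}


def global_metrics_for_stack(
    stack: BinaryNetworkStack,
    null_spec: NullEnsembleSpec | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One row per sparsity level with the global metric set.

    Small-world ratios are included when a null-ensemble spec is given; the
    generator is advanced per level so the whole table is reproducible from
    one seed.
    """
    rows = []
    for i, (s, adj) in enumerate(stack):
        row = {"sparsity": float(s), **global_metrics_at(adj)}
        if null_spec is not None:
            if rng is None:
                rng = np.random.default_rng(null_spec.seed)
            try:
                row.update(small_world_at(adj, null_spec, rng))
            except MetricUndefinedError:
                # degenerate regime (tiny graphs whose nulls have no
                # triangles); ratios undefined at this level
                row.update({"gamma": np.nan, "lambda": np.nan, "sigma": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def nodal_metrics_for_stack(stack: BinaryNetworkStack, labels=None) -> pd.DataFrame:
    """Long table: one row per (node, sparsity) with DC, BC, NE."""
    rows = []
    n = stack.n_nodes
    labels = list(labels) if labels is not None else [f"ROI{i + 1:03d}" for i in range(n)]
    for s, adj in stack:
        dist = shortest_path_matrix(adj)
        dc = degree_centrality(adj)
        bc = betweenness_centrality(adj)
        ne = nodal_efficiency(dist)
        for i in range(n):
            rows.append({
                "node": i, "label": labels[i], "sparsity": float(s),
                "DC": int(dc[i]), "BC": float(bc[i]), "NE": float(ne[i]),
            })
    return pd.DataFrame(rows)


def auc_summary(
    global_df: pd.DataFrame,
    nodal_df: pd.DataFrame | None = None,
) -> dict:
    """AUC of every metric curve over the sparsity grid.

    Keys: ``<metric>_auc`` for global metrics, ``<metric>_auc_node<i>`` for
    nodal ones.
    """
    grid = global_df["sparsity"].to_numpy()
    out = {}
    for m in GLOBAL_METRICS:
        if m in global_df.columns:
            vals = global_df[m].to_numpy()
            ok = np.isfinite(vals)
            if ok.all():
                out[f"{m}_auc"] = auc(vals, grid)
            elif ok.sum() >= 2:
                # integrate over the defined sub-grid (degenerate low-S levels
                # of very small graphs are excluded)
                out[f"{m}_auc"] = auc(vals[ok], grid[ok])
            else:
                out[f"{m}_auc"] = np.nan
    if nodal_df is not None:
        for m in NODAL_METRICS:
            wide = nodal_df.pivot(index="sparsity", columns="node", values=m).sort_index()
            for node in wide.columns:
                out[f"{m}_auc_node{node}"] = auc(
                    wide[node].to_numpy(), wide.index.to_numpy()
                )
    return out
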