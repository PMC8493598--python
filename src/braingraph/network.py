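"""Binary functional-network construction.

Pearson correlation between every pair of regional time series, Fisher Z
transformation, and conversion to binary undirected graphs at a grid of
sparsity levels. Sparsity S is the fraction of realized edges among the
R(R-1)/2 possible ones; thresholding at fixed sparsity equalizes edge count
across subjects regardless of overall correlation strength. Edges are chosen
by a single global ranking of Z values, which makes the edge sets nested
across the grid by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._aal import default_labels
from .errors import InputError, ParameterError

DEFAULT_GRID_START = 0.05
DEFAULT_GRID_STOP = 0.50
DEFAULT_GRID_STEP = 0.01


def sparsity_grid(
    start: float = DEFAULT_GRID_START,
    stop: float = DEFAULT_GRID_STOP,
    step: float = DEFAULT_GRID_STEP,
) -> np.ndarray:
    """Inclusive sparsity grid (default 0.05, 0.06, ..., 0.50 — 46 levels)."""
    if not (0 < start < stop < 1):
        raise ParameterError("grid bounds must satisfy 0 < start < stop < 1")
    n = int(round((stop - start) / step)) + 1
    grid = np.round(start + step * np.arange(n), 10)
    if grid[-1] > stop + 1e-12:
        grid = grid[:-1]
    return grid


def correlation_matrix(ts: np.ndarray, labels=None) -> np.ndarray:
    """Pairwise Pearson correlation of regional time series (columns).

    A constant column has no defined correlation; the error names the ROI.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise InputError("time series must be 2-D (time x regions)")
    t, r = ts.shape
    if t < 3:
        raise InputError("need at least 3 time points")
    if r < 3:
        raise InputError("need at least 3 regions")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        labels = labels or default_labels(r)
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise InputError(f"constant time series for ROI(s): {', '.join(bad)}")
    corr = np.corrcoef(ts, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(corr: np.ndarray) -> np.ndarray:
    """Elementwise Fisher Z transform z = arctanh(r); diagonal stored as 0.

    An off-diagonal |r| = 1 can only arise from duplicated regions and is
    rejected.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise InputError("correlation matrix must be square")
    off = ~np.eye(corr.shape[0], dtype=bool)
    if np.any(np.abs(corr[off]) >= 1.0):
        raise InputError("off-diagonal |r| = 1: duplicated ROI time series?")
    z = np.zeros_like(corr)
    z[off] = np.arctanh(corr[off])
    return z


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def edge_count_for_sparsity(sparsity: float, n_nodes: int) -> int:
    """Number of edges at a sparsity level: round(S * R(R-1)/2), half-up."""
    if not (0 < sparsity < 1):
        raise ParameterError(f"sparsity must be in (0, 1), got {sparsity}")
    e_max = n_nodes * (n_nodes - 1) // 2
    k = _round_half_up(sparsity * e_max)
    if k == 0:
        raise ParameterError(
            f"sparsity {sparsity} yields 0 edges on {n_nodes} nodes"
        )
    return k


def rank_edges(z: np.ndarray, mode: str = "positive") -> tuple[np.ndarray, np.ndarray]:
    """Global edge ranking for thresholding.

    Returns upper-triangle node pairs ordered by descending score, ties
    broken by lexicographic node-pair order so runs are reproducible, plus
    the scores in that order. ``mode='positive'`` ranks raw Z (negative
    correlations can never become edges); ``mode='absolute'`` ranks |Z|.
    """
    if mode not in ("positive", "absolute"):
        raise ParameterError(f"unknown threshold mode {mode!r}")
    r = z.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    score = z[iu, ju] if mode == "positive" else np.abs(z[iu, ju])
    order = np.lexsort((ju, iu, -score))
    return np.column_stack([iu[order], ju[order]]), score[order]


def threshold_by_sparsity(
    z: np.ndarray, sparsity: float, mode: str = "positive"
) -> np.ndarray:
    """Binary adjacency with round(S * R(R-1)/2) edges: the top-ranked pairs.

    Under ``positive`` mode only pairs with Z > 0 may become edges; if fewer
    than K such pairs exist the graph keeps all of them and a warning is
    issued.
    """
    z = np.asarray(z, dtype=float)
    r = z.shape[0]
    k = edge_count_for_sparsity(sparsity, r)
    pairs, scores = rank_edges(z, mode)
    eligible = scores > 0 if mode == "positive" else np.ones(scores.size, bool)
    n_take = min(k, int(eligible.sum()))
    if n_take < k:
        warnings.warn(
            f"only {n_take} positive-Z pairs available for K = {k} edges",
            stacklevel=2,
        )
    adj = np.zeros((r, r), dtype=bool)
    sel = pairs[:n_take]
    adj[sel[:, 0], sel[:, 1]] = True
    adj |= adj.T
    return adj


@dataclass
class BinaryNetworkStack:
    """Per-subject stack of binary graphs indexed by sparsity level.

    Built from one global edge ranking, so edge sets are nested: increasing
    sparsity only ever adds edges.
    """

    n_nodes: int
    grid: np.ndarray
    ranked_pairs: np.ndarray     # (E_max, 2) node pairs, best first
    edge_counts: np.ndarray      # edges realized at each grid level

    def adjacency(self, idx: int) -> np.ndarray:
        """Dense boolean adjacency of the graph at grid position ``idx``."""
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        sel = self.ranked_pairs[: self.edge_counts[idx]]
        adj[sel[:, 0], sel[:, 1]] = True
        adj |= adj.T
        return adj

    def __len__(self) -> int:
        return len(self.grid)

    def __iter__(self):
        for i in range(len(self.grid)):
            yield self.grid[i], self.adjacency(i)

    def edge_list(self, idx: int) -> np.ndarray:
        """(K, 2) array of 0-based node pairs at grid position ``idx``."""
        return self.ranked_pairs[: self.edge_counts[idx]].copy()


def build_stack(
    z: np.ndarray, grid: np.ndarray | None = None, mode: str = "positive"
) -> BinaryNetworkStack:
    """Threshold a Z matrix over the whole sparsity grid."""
    z = np.asarray(z, dtype=float)
    if grid is None:
        grid = sparsity_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ParameterError("grid values must lie in (0, 1)")
    r = z.shape[0]
    pairs, scores = rank_edges(z, mode)
    eligible = scores > 0 if mode == "positive" else np.ones(scores.size, bool)
    n_eligible = int(eligible.sum())
    counts = np.empty(grid.size, dtype=int)
    for i, s in enumerate(grid):
        k = edge_count_for_sparsity(float(s), r)
        counts[i] = min(k, n_eligible)
        if counts[i] < k:
            warnings.warn(
                f"sparsity {s}: only {counts[i]} positive-Z pairs for K = {k}",
                stacklevel=2,
            )
    return BinaryNetworkStack(
        n_nodes=r, grid=grid, ranked_pairs=pairs, edge_counts=counts
    )
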