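"""Spatiotemporal cluster-based permutation tests on TRF weights.

Paired two-condition contrasts of (channel x lag) weight maps across
participants are tested with the max-cluster-statistic permutation
scheme: a paired t is computed per (channel, lag); samples exceeding the
two-tailed critical t at the cluster-forming alpha (default 0.05) are
grouped into spatiotemporally connected clusters (channel adjacency from
sensor distances, lag adjacency between consecutive samples, clusters of
one t sign); each cluster's statistic is the signed sum of its t values.
The null distribution of the maximum absolute cluster statistic is built
by random within-participant condition-label sign flips, and each
observed cluster's p-value is ``(b + 1) / (m + 1)`` where ``b`` counts
permutations whose maximum reaches the observed statistic — the observed
labelling is included, so the smallest attainable p is ``1/(m + 1)``.
The Monte-Carlo uncertainty of each p is ``sqrt(p (1-p) / m)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ChannelAdjacency",
    "ClusterResult",
    "adjacency_from_positions",
    "paired_cluster_permutation",
]


@dataclass(frozen=True)
class ChannelAdjacency:
    """Symmetric channel neighborhood structure."""

    neighbors: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        for i, ns in enumerate(self.neighbors):
            if i in ns:
                raise ValueError("self-neighbors are not allowed")
            for j in ns:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)

    def matrix(self) -> sparse.csr_matrix:
        rows, cols = [], []
        for i, ns in enumerate(self.neighbors):
            for j in ns:
                rows.append(i)
                cols.append(j)
        data = np.ones(len(rows), dtype=np.int8)
        n = self.n_channels
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def adjacency_from_positions(
    positions: np.ndarray, threshold: float
) -> ChannelAdjacency:
    """Neighbors are channel pairs closer than ``threshold`` (same units
    as the positions; the shipped montage lives on the unit sphere)."""
    pos = np.asarray(positions, float)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.isfinite(pos).all():
        raise ValueError("non-finite positions")
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    close = (d < threshold) & ~np.eye(pos.shape[0], dtype=bool)
    neighbors = tuple(frozenset(np.flatnonzero(row)) for row in close)
    if any(len(ns) == 0 for ns in neighbors):
        warnings.warn("isolated channel(s): threshold below the minimal "
                      "inter-channel distance", stacklevel=2)
    return ChannelAdjacency(neighbors)


@dataclass(frozen=True)
class ClusterResult:
    """Observed clusters with permutation p-values.

    ``clusters`` holds, per cluster, an array of (channel, lag) index
    pairs; ``cluster_stats`` the signed t-sums; ``p_values`` the
    permutation p-values and ``mc_sd`` their Monte-Carlo SDs.
    """

    clusters: tuple[np.ndarray, ...]
    cluster_stats: np.ndarray
    p_values: np.ndarray
    mc_sd: np.ndarray
    n_permutations: int
    t_map: np.ndarray  # (n_channels, n_lags) observed paired t
    t_critical: float

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p < alpha]


def _spatiotemporal_graph(
    adjacency: ChannelAdjacency, n_lags: int
) -> sparse.csr_matrix:
    """Union graph: nodes (c, l) flattened c * n_lags + l; edges between
    lag-consecutive samples of a channel and same-lag neighbor channels."""
    n_ch = adjacency.n_channels
    rows, cols = [], []
    # temporal edges
    for c in range(n_ch):
        base = c * n_lags
        idx = np.arange(n_lags - 1)
        rows.extend(base + idx)
        cols.extend(base + idx + 1)
    # spatial edges
    for c, ns in enumerate(adjacency.neighbors):
        for j in ns:
            if j > c:
                idx = np.arange(n_lags)
                rows.extend(c * n_lags + idx)
                cols.extend(j * n_lags + idx)
    n = n_ch * n_lags
    g = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return g + g.T


def _max_cluster_stat(
    t_flat: np.ndarray, graph: sparse.csr_matrix, t_crit: float
) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        nodes = np.flatnonzero(sign * t_flat > t_crit)
        if nodes.size == 0:
            continue
        sub = graph[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        sums = np.bincount(labels, weights=np.abs(t_flat[nodes]),
                           minlength=n_comp)
        best = max(best, sums.max(initial=0.0))
    return best


def _observed_clusters(
    t_flat: np.ndarray, graph: sparse.csr_matrix, t_crit: float, n_lags: int
) -> tuple[list[np.ndarray], list[float]]:
    members, stats_ = [], []
    for sign in (1.0, -1.0):
        nodes = np.flatnonzero(sign * t_flat > t_crit)
        if nodes.size == 0:
            continue
        sub = graph[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            mem = nodes[labels == k]
            members.append(np.column_stack([mem // n_lags, mem % n_lags]))
            stats_.append(float(t_flat[mem].sum()))
    return members, stats_


def paired_cluster_permutation(
    A: np.ndarray,
    B: np.ndarray,
    adjacency: ChannelAdjacency,
    cluster_alpha: float = 0.05,
    n_permutations: int = 5000,
    seed: int = 0,
) -> ClusterResult:
    """Paired spatiotemporal cluster permutation test of A vs B.

    ``A`` and ``B`` are (n_participants, n_channels, n_lags) arrays of one
    weight map per participant and condition.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("condition arrays must have identical shapes")
    n, n_ch, n_lags = A.shape
    if n < 5:
        raise ValueError("need at least 5 participants for a paired test")
    if n_ch != adjacency.n_channels:
        raise ValueError("adjacency channel count does not match the data")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse",
                      stacklevel=2)

    D = (A - B).reshape(n, -1)
    t_crit = float(stats.t.ppf(1 - cluster_alpha / 2, n - 1))
    graph = _spatiotemporal_graph(adjacency, n_lags)

    sumsq = (D**2).sum(axis=0)

    def t_from_signs(signs: np.ndarray) -> np.ndarray:
        # sign flips leave sum of squares unchanged, so t follows from the
        # flipped mean alone
        mean = signs @ D / n
        var = (sumsq - n * mean**2) / (n - 1)
        var = np.maximum(var, 1e-300)
        return mean / np.sqrt(var / n)

    t_obs = t_from_signs(np.ones((1, n)))[0]
    members, cstats = _observed_clusters(t_obs, graph, t_crit, n_lags)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    chunk = max(1, min(512, n_permutations))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        signs = rng.choice((-1.0, 1.0), size=(m, n))
        t_perm = t_from_signs(signs)
        for i in range(m):
            null_max[done + i] = _max_cluster_stat(t_perm[i], graph, t_crit)
        done += m

    cstats_arr = np.asarray(cstats)
    if cstats_arr.size:
        b = (null_max[None, :] >= np.abs(cstats_arr)[:, None]).sum(axis=1)
        p = (b + 1) / (n_permutations + 1)
    else:
        p = np.empty(0)
    mc_sd = np.sqrt(p * (1 - p) / n_permutations) if p.size else np.empty(0)

    order = np.argsort(-np.abs(cstats_arr)) if cstats_arr.size else []
    return ClusterResult(
        tuple(members[i] for i in order),
        cstats_arr[order] if cstats_arr.size else cstats_arr,
        p[order] if cstats_arr.size else p,
        mc_sd[order] if cstats_arr.size else mc_sd,
        n_permutations,
        t_obs.reshape(n_ch, n_lags),
        t_crit,
    )
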