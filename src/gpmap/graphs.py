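"""Low-level graph routines on CSR adjacency matrices.

Hand-rolled (rather than delegated wholesale to a graph library) because
the statistics must follow specific formulas: the clustering coefficient
is the mean of local clustering with degree-deficient nodes contributing
zero, and assortativity is the edge-endpoint-degree Pearson correlation,
returning NaN for regular graphs.
"""

from __future__ import annotations

import sys
from typing import Iterable

import numpy as np
import scipy.sparse as sp


def bfs_distances(adj: sp.csr_matrix, source: int) -> np.ndarray:
    """Unweighted single-source distances; −1 where unreachable."""
    n = adj.shape[0]
    indptr, indices = adj.indptr, adj.indices
    dist = np.full(n, -1, dtype=np.int32)
    dist[source] = 0
    seen = np.zeros(n, dtype=bool)
    seen[source] = True
    frontier = np.array([source], dtype=np.int64)
    d = 0
    while frontier.size:
        d += 1
        starts = indptr[frontier]
        counts = indptr[frontier + 1] - starts
        total = int(counts.sum())
        if total == 0:
            break
        # gather all neighbor indices of the frontier in one shot
        offsets = np.repeat(starts - np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
        nbrs = indices[np.arange(total, dtype=np.int64) + offsets]
        new = nbrs[~seen[nbrs]]
        if new.size == 0:
            break
        seen[new] = True
        frontier = np.unique(new)
        dist[frontier] = d
    return dist


def path_stats(adj: sp.csr_matrix, progress: bool = False) -> tuple[int, float]:
    """Exact (diameter, characteristic path length) via batched bitset BFS.

    Runs breadth-first searches from every node, 64 sources at a time:
    the wavefronts of a batch are stored as uint64 bitmasks per node and
    advanced with a gather + ``bitwise_or.reduceat`` sweep over the CSR
    structure.  The characteristic path length is the mean shortest-path
    distance over distinct pairs (identical for ordered and unordered
    pairs).  Raises on disconnected graphs.
    """
    n = adj.shape[0]
    if n == 1:
        return 0, 0.0
    indptr = adj.indptr.astype(np.int64)
    indices = adj.indices.astype(np.int64)
    empty_rows = np.flatnonzero(np.diff(indptr) == 0)
    total = 0
    diameter = 0
    reached = 0  # (source, node) pairs reached, for connectivity check
    n_batches = (n + 63) // 64
    for b in range(n_batches):
        lo = b * 64
        hi = min(lo + 64, n)
        width = hi - lo
        state = np.zeros(n, dtype=np.uint64)
        state[lo:hi] = np.uint64(1) << np.arange(width, dtype=np.uint64)
        reached += width
        d = 0
        while True:
            d += 1
            gathered = state[indices]
            nxt = np.bitwise_or.reduceat(gathered, indptr[:-1])
            if empty_rows.size:
                nxt[empty_rows] = 0  # reduceat misbehaves on empty slices
            new = nxt & ~state
            cnt = int(np.bitwise_count(new).sum())
            if cnt == 0:
                break
            total += d * cnt
            reached += cnt
            state |= new
            if d > diameter:
                diameter = d
        if progress and b % 64 == 0:
            print(f"  bfs batch {b}/{n_batches}", file=sys.stderr)
    if reached != n * n:
        raise ValueError("graph is disconnected")
    return diameter, total / (n * (n - 1))


def local_clustering(adj: sp.csr_matrix, block: int = 2048) -> np.ndarray:
    """Per-node clustering c_i = 2 T_i / (k_i (k_i - 1)); 0 when k_i < 2."""
    n = adj.shape[0]
    a = adj.astype(np.float32)
    deg = np.diff(adj.indptr)
    tri = np.empty(n, dtype=np.float64)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        # paths of length 2 from i that close into an edge => 2 * triangles
        tri[lo:hi] = np.asarray((a[lo:hi] @ a).multiply(a[lo:hi]).sum(axis=1)).ravel() / 2.0
    c = np.zeros(n, dtype=np.float64)
    ok = deg >= 2
    c[ok] = 2.0 * tri[ok] / (deg[ok] * (deg[ok] - 1.0))
    return c


def clustering_eq1(adj: sp.csr_matrix) -> float:
    """Mean local clustering over all nodes (degree < 2 contributes 0)."""
    if adj.shape[0] == 0:
        return float("nan")
    return float(local_clustering(adj).mean())


def edge_endpoints(adj: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Each undirected edge once, as (u, v) index arrays."""
    coo = sp.triu(adj).tocoo()
    return coo.row.astype(np.int64), coo.col.astype(np.int64)


def assortativity_eq2(adj: sp.csr_matrix) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    NaN when the degree variance over edge endpoints is zero (regular
    graphs) or when there are no edges.
    """
    u, v = edge_endpoints(adj)
    if len(u) == 0:
        return float("nan")
    deg = np.diff(adj.indptr).astype(np.float64)
    j, kk = deg[u], deg[v]
    mean_prod = np.mean(j * kk)
    mean_sum = np.mean(0.5 * (j + kk))
    mean_sq = np.mean(0.5 * (j**2 + kk**2))
    den = mean_sq - mean_sum**2
    if den == 0:
        return float("nan")
    return float((mean_prod - mean_sum**2) / den)


def connected_components(adj: sp.csr_matrix) -> tuple[int, np.ndarray]:
    return sp.csgraph.connected_components(adj, directed=False)


def neighborhoods(adj: sp.csr_matrix, nodes: np.ndarray) -> np.ndarray:
    """Union of the neighbor sets of ``nodes`` (sorted unique indices)."""
    nodes = np.asarray(nodes, dtype=np.int64)
    if nodes.size == 0:
        return np.empty(0, dtype=np.int64)
    chunks = [adj.indices[adj.indptr[i] : adj.indptr[i + 1]] for i in nodes]
    return np.unique(np.concatenate(chunks)) if chunks else np.empty(0, dtype=np.int64)
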