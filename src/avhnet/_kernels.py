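"""Low-level numba kernels for binary-graph metrics and degree-preserving rewiring.

These operate on dense uint8 adjacency matrices (undirected, zero diagonal).
They exist because the null-model normalization evaluates clustering and path
length on ~10^4-10^5 rewired graphs per analysis run; the pure-Python
equivalents in :mod:`avhnet.graph_metrics` docstrings describe the same
definitions and the test suite checks agreement with networkx.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bfs_distances",
    "clustering_mean",
    "local_efficiency_mean",
    "rewire_degree_preserving",
    "null_cp_lp_ensemble",
]


@njit(cache=True)
def bfs_distances(adj):
    """All-pairs shortest-path lengths by BFS; -1 marks unreachable pairs."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[s, s] = 0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def component_labels(adj):
    """Connected-component label per node (isolated nodes get their own)."""
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    cur = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        labels[s] = cur
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            for v in range(n):
                if adj[u, v] != 0 and labels[v] < 0:
                    labels[v] = cur
                    queue[tail] = v
                    tail += 1
        cur += 1
    return labels


@njit(cache=True)
def lp_eglob_from_dist(dist):
    """(lp, eglob) from a BFS distance matrix.

    lp averages finite off-diagonal distances (disconnected pairs excluded);
    returns lp = nan when no pair is connected. eglob averages 1/d over all
    pairs with 1/inf = 0.
    """
    n = dist.shape[0]
    s_lp = 0.0
    k_lp = 0
    s_eg = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = dist[i, j]
            if d > 0:
                s_lp += d
                k_lp += 1
                s_eg += 1.0 / d
    n_pairs = n * (n - 1)
    eglob = s_eg / n_pairs if n_pairs > 0 else 0.0
    lp = s_lp / k_lp if k_lp > 0 else np.nan
    return lp, eglob


@njit(cache=True)
def clustering_mean(adj):
    """Mean over nodes of 2*triangles/(deg*(deg-1)); deg<2 nodes contribute 0."""
    n = adj.shape[0]
    total = 0.0
    nb = np.empty(n, dtype=np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nb[a], nb[b]] != 0:
                    tri += 1
        total += 2.0 * tri / (k * (k - 1))
    return total / n


@njit(cache=True)
def local_efficiency_mean(adj):
    """Mean nodal efficiency of each node's neighborhood subgraph."""
    n = adj.shape[0]
    nb = np.empty(n, dtype=np.int32)
    total = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.zeros((k, k), dtype=np.uint8)
        for a in range(k):
            for b in range(k):
                if a != b and adj[nb[a], nb[b]] != 0:
                    sub[a, b] = 1
        dist = bfs_distances(sub)
        s = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and dist[a, b] > 0:
                    s += 1.0 / dist[a, b]
        total += s / (k * (k - 1))
    return total / n


@njit(cache=True)
def _rewire_inplace(adj, edges, n_target, max_attempts):
    """Attempt double-edge swaps in place; returns number of successful swaps.

    Consumes the numba global RNG stream (seed before calling)."""
    n_edges = edges.shape[0]
    successes = 0
    attempts = 0
    while successes < n_target and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(0, n_edges)
        e2 = np.random.randint(0, n_edges)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # require four distinct endpoints and absence of the proposed edges
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] != 0 or adj[c, b] != 0:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        successes += 1
    return successes


@njit(cache=True)
def rewire_degree_preserving(adj, n_target, max_attempts, seed):
    """Maslov-Sneppen rewiring: returns (new adjacency, successful swap count)."""
    np.random.seed(seed)
    out = adj.copy()
    n = out.shape[0]
    n_edges = 0
    for i in range(n):
        for j in range(i + 1, n):
            if out[i, j] != 0:
                n_edges += 1
    edges = np.empty((n_edges, 2), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if out[i, j] != 0:
                edges[k, 0] = i
                edges[k, 1] = j
                k += 1
    successes = _rewire_inplace(out, edges, n_target, max_attempts)
    return out, successes


@njit(cache=True)
def null_cp_lp_ensemble(adj, n_null, n_burn, n_thin, max_attempts, seed):
    """cp and lp over a chained ensemble of degree-preserving null graphs.

    One Markov chain of double edge swaps: ``n_burn`` successful swaps of
    burn-in from the source graph, then a snapshot every ``n_thin``
    successful swaps. Returns (cp[n_null], lp[n_null], total_successes).
    """
    np.random.seed(seed)
    state = adj.copy()
    n = state.shape[0]
    n_edges = 0
    for i in range(n):
        for j in range(i + 1, n):
            if state[i, j] != 0:
                n_edges += 1
    edges = np.empty((n_edges, 2), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if state[i, j] != 0:
                edges[k, 0] = i
                edges[k, 1] = j
                k += 1
    cps = np.empty(n_null, dtype=np.float64)
    lps = np.empty(n_null, dtype=np.float64)
    total = _rewire_inplace(state, edges, n_burn, max_attempts)
    for r in range(n_null):
        total += _rewire_inplace(state, edges, n_thin,
                                 max(max_attempts // 10, 100))
        cps[r] = clustering_mean(state)
        dist = bfs_distances(state)
        lp, _ = lp_eglob_from_dist(dist)
        lps[r] = lp
    return cps, lps, total
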