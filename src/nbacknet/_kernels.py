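"""Low-level graph kernels (numba-compiled).

All kernels operate on dense ``uint8`` adjacency matrices of simple,
undirected, unweighted graphs.  Networks here are small (80 cortical
regions), so dense storage plus on-the-fly CSR conversion is both the
simplest and the fastest layout; the JIT compilation pays for itself in
the surrogate-ensemble loops, which dominate every cohort-level run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bfs_distances",
    "is_connected",
    "degree_and_triangles",
    "clustering_terms",
    "path_stats",
    "graph_cl_stats",
    "local_efficiency_bitset",
    "betweenness_values",
    "rewire_inplace",
    "surrogate_cl",
]

_SEED_MASK = np.int64(0x7FFFFFFF)


@njit(cache=True)
def _csr(adj):
    """Neighbor lists (indptr, indices) of a dense adjacency matrix."""
    n = adj.shape[0]
    indptr = np.zeros(n + 1, np.int32)
    for i in range(n):
        d = 0
        for j in range(n):
            if adj[i, j]:
                d += 1
        indptr[i + 1] = indptr[i] + d
    indices = np.empty(indptr[n], np.int32)
    for i in range(n):
        p = indptr[i]
        for j in range(n):
            if adj[i, j]:
                indices[p] = j
                p += 1
    return indptr, indices


@njit(cache=True)
def bfs_distances(adj):
    """All-pairs shortest hop counts; -1 marks unreachable pairs."""
    n = adj.shape[0]
    indptr, indices = _csr(adj)
    dist = np.full((n, n), -1, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for p in range(indptr[u], indptr[u + 1]):
                v = indices[p]
                if dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def bfs_sigma(adj):
    """All-pairs (distance, number-of-shortest-paths) matrices."""
    n = adj.shape[0]
    indptr, indices = _csr(adj)
    dist = np.full((n, n), -1, np.int32)
    sigma = np.zeros((n, n))
    queue = np.empty(n, np.int32)
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for p in range(indptr[u], indptr[u + 1]):
                v = indices[p]
                if dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
                if dist[s, v] == du + 1:
                    sigma[s, v] += sigma[s, u]
    return dist, sigma


@njit(cache=True)
def is_connected(adj):
    n = adj.shape[0]
    if n == 0:
        return True
    seen = np.zeros(n, np.uint8)
    queue = np.empty(n, np.int32)
    seen[0] = 1
    queue[0] = 0
    head, tail = 0, 1
    while head < tail:
        u = queue[head]
        head += 1
        for v in range(n):
            if adj[u, v] and not seen[v]:
                seen[v] = 1
                queue[tail] = v
                tail += 1
    return tail == n


@njit(cache=True)
def degree_and_triangles(adj):
    """Per-node degree k_i and triangle count E_i."""
    n = adj.shape[0]
    deg = np.zeros(n, np.int64)
    tri = np.zeros(n, np.int64)
    nbr = np.empty(n, np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbr[k] = j
                k += 1
        deg[i] = k
        t = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbr[a], nbr[b]]:
                    t += 1
        tri[i] = t
    return deg, tri


@njit(cache=True)
def clustering_terms(adj):
    """Per-node local clustering 2E_i/(k_i(k_i-1)); 0 where k_i < 2."""
    n = adj.shape[0]
    deg, tri = degree_and_triangles(adj)
    out = np.zeros(n)
    for i in range(n):
        k = deg[i]
        if k >= 2:
            out[i] = 2.0 * tri[i] / (k * (k - 1.0))
    return out


@njit(cache=True)
def path_stats(dist):
    """(L, E_global, connected) from a distance matrix.

    L is the mean hop count over ordered pairs and is NaN when any pair
    is unreachable; E_global averages 1/d with unreachable pairs
    contributing zero.
    """
    n = dist.shape[0]
    if n < 2:
        return np.nan, 0.0, True
    total = 0.0
    eff = 0.0
    connected = True
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = dist[i, j]
            if d < 0:
                connected = False
            else:
                total += d
                eff += 1.0 / d
    npairs = n * (n - 1.0)
    L = total / npairs if connected else np.nan
    return L, eff / npairs, connected


@njit(cache=True)
def betweenness_values(adj):
    """Raw betweenness b_i (Brandes accumulation, fractional counting).

    Each unordered pair {s, t} with s != i != t contributes
    sigma_st(i)/sigma_st; unreachable pairs contribute nothing.
    """
    n = adj.shape[0]
    indptr, indices = _csr(adj)
    bc = np.zeros(n)
    dist = np.empty(n, np.int32)
    sigma = np.empty(n)
    delta = np.empty(n)
    order = np.empty(n, np.int32)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
            sigma[i] = 0.0
            delta[i] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            u = order[head]
            head += 1
            for p in range(indptr[u], indptr[u + 1]):
                v = indices[p]
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    order[tail] = v
                    tail += 1
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        for idx in range(tail - 1, 0, -1):
            w = order[idx]
            coeff = (1.0 + delta[w]) / sigma[w]
            for p in range(indptr[w], indptr[w + 1]):
                v = indices[p]
                if dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_ZERO = np.uint64(0)
_ONE = np.uint64(1)


@njit(cache=True)
def _popcount64(x):
    x = x - ((x >> _ONE) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


@njit(cache=True)
def _to_words(adj):
    """Pack adjacency rows into uint64 bitsets."""
    n = adj.shape[0]
    nw = (n + 63) // 64
    words = np.zeros((n, nw), np.uint64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                words[i, j >> 6] |= _ONE << np.uint64(j & 63)
    return words


@njit(cache=True)
def _bitset_levels(words, mask, sources, n_words, Lsum_Esum):
    """Accumulate BFS level sums within a node mask (bitset frontier).

    For every source, counts nodes first reached at each hop level and
    accumulates sum(level * count) and sum(count / level); returns the
    total number of (ordered) reached pairs so callers can detect
    unreachable ones.
    """
    reached_pairs = 0
    visited = np.empty(n_words, np.uint64)
    new = np.empty(n_words, np.uint64)
    frontier_nodes = np.empty(words.shape[0], np.int32)
    for si in range(sources.shape[0]):
        s = sources[si]
        for w in range(n_words):
            visited[w] = _ZERO
        visited[s >> 6] |= _ONE << np.uint64(s & 63)
        frontier_nodes[0] = s
        fn = 1
        level = 0
        while fn > 0:
            for w in range(n_words):
                new[w] = _ZERO
            for k in range(fn):
                v = frontier_nodes[k]
                for w in range(n_words):
                    new[w] |= words[v, w]
            level += 1
            fn = 0
            for w in range(n_words):
                x = new[w] & mask[w] & ~visited[w]
                visited[w] |= x
                base = w << 6
                while x:
                    b = x & (_ZERO - x)
                    frontier_nodes[fn] = base + np.int64(_popcount64(b - _ONE))
                    fn += 1
                    x ^= b
            if fn > 0:
                Lsum_Esum[0] += level * fn
                Lsum_Esum[1] += fn / level
                reached_pairs += fn
    return reached_pairs


@njit(cache=True)
def graph_cl_stats(adj):
    """(C, L, E_global, connected) of a binary graph via bitset BFS.

    C follows the degree<2 -> 0 convention; L is NaN when any pair is
    unreachable; unreachable pairs contribute 0 to E_global.
    """
    n = adj.shape[0]
    if n < 2:
        return 0.0, np.nan, 0.0, True
    words = _to_words(adj)
    nw = words.shape[1]
    Csum = 0.0
    for i in range(n):
        k = 0
        for w in range(nw):
            k += np.int64(_popcount64(words[i, w]))
        if k < 2:
            continue
        t2 = 0
        for j in range(n):
            if adj[i, j]:
                for w in range(nw):
                    t2 += np.int64(_popcount64(words[i, w] & words[j, w]))
        Csum += t2 / (k * (k - 1.0))
    mask = np.empty(nw, np.uint64)
    for w in range(nw):
        mask[w] = ~_ZERO
    if n & 63:
        mask[nw - 1] = (_ONE << np.uint64(n & 63)) - _ONE
    sources = np.arange(n).astype(np.int64)
    acc = np.zeros(2)
    reached = _bitset_levels(words, mask, sources, nw, acc)
    npairs = n * (n - 1.0)
    connected = reached == n * (n - 1)
    L = acc[0] / npairs if connected else np.nan
    return Csum / n, L, acc[1] / npairs, connected


@njit(cache=True)
def local_efficiency_bitset(adj):
    """Mean global efficiency of neighbor subgraphs, bitset BFS."""
    n = adj.shape[0]
    if n == 0:
        return 0.0
    words = _to_words(adj)
    nw = words.shape[1]
    total = 0.0
    for i in range(n):
        k = 0
        for w in range(nw):
            k += np.int64(_popcount64(words[i, w]))
        if k < 2:
            continue
        sources = np.empty(k, np.int64)
        c = 0
        for j in range(n):
            if adj[i, j]:
                sources[c] = j
                c += 1
        acc = np.zeros(2)
        _bitset_levels(words, words[i], sources, nw, acc)
        total += acc[1] / (k * (k - 1.0))
    return total / n


@njit(cache=True)
def rewire_inplace(adj, swap_factor, seed, per_swap_check):
    """Maslov-Sneppen double-edge-swap randomization, in place.

    Attempts ``swap_factor * |E|`` swaps; a candidate is rejected if it
    would create a self-loop or multi-edge.  With ``per_swap_check`` the
    graph's connectedness is re-verified after every accepted swap and
    the swap reverted on failure.  Returns the number of accepted swaps.
    """
    np.random.seed(seed)
    n = adj.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                m += 1
    if m < 2:
        return 0
    eu = np.empty(m, np.int32)
    ev = np.empty(m, np.int32)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                eu[c] = i
                ev[c] = j
                c += 1
    accepted = 0
    attempts = swap_factor * m
    pick_i = np.random.randint(0, m, attempts)
    pick_j = np.random.randint(0, m, attempts)
    flip = np.random.randint(0, 2, attempts)
    for t in range(attempts):
        i = pick_i[t]
        j = pick_j[t]
        if i == j:
            continue
        a, b = eu[i], ev[i]
        cc, d = eu[j], ev[j]
        if flip[t] == 1:
            cc, d = d, cc
        if a == cc or a == d or b == cc or b == d:
            continue
        if adj[a, d] or adj[cc, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[cc, d] = 0
        adj[d, cc] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[cc, b] = 1
        adj[b, cc] = 1
        if per_swap_check and not is_connected(adj):
            adj[a, d] = 0
            adj[d, a] = 0
            adj[cc, b] = 0
            adj[b, cc] = 0
            adj[a, b] = 1
            adj[b, a] = 1
            adj[cc, d] = 1
            adj[d, cc] = 1
        else:
            eu[i], ev[i] = a, d
            eu[j], ev[j] = cc, b
            accepted += 1
    return accepted


@njit(cache=True)
def surrogate_cl(adj, n_surrogates, swap_factor, seeds, per_swap_check,
                 max_retries):
    """Clustering and path length of degree-preserving surrogates.

    Without per-swap checking, each surrogate is rewired freely and its
    connectedness verified afterwards; disconnected draws are retried
    with a perturbed seed, falling back to per-swap checking if
    ``max_retries`` whole-graph retries all fail.  Returns per-surrogate
    arrays (C, L).
    """
    C = np.empty(n_surrogates)
    L = np.empty(n_surrogates)
    for k in range(n_surrogates):
        surr = adj.copy()
        if per_swap_check:
            rewire_inplace(surr, swap_factor, seeds[k], True)
        else:
            ok = False
            for r in range(max_retries):
                surr = adj.copy()
                s = (seeds[k] + np.int64(7919) * np.int64(r)) & _SEED_MASK
                rewire_inplace(surr, swap_factor, s, False)
                if is_connected(surr):
                    ok = True
                    break
            if not ok:
                surr = adj.copy()
                rewire_inplace(surr, swap_factor, seeds[k], True)
        Ck, Lk, _, _ = graph_cl_stats(surr)
        C[k] = Ck
        L[k] = Lk
    return C, L
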