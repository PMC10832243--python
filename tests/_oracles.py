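"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths (and the library calls) they check:
betweenness is obtained by enumerating every shortest path explicitly,
closeness and degree from raw BFS distances, the hypergeometric tail by
enumerating draws, and BH by the textbook step-up loop.
"""
from collections import deque
from itertools import combinations
from math import comb


def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _adjacency(graph):
    return {n: sorted(graph.neighbors(n)) for n in graph}


def all_shortest_paths(adj, s, t):
    """Every shortest s-t path, by DFS over the BFS predecessor DAG."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    preds = {v: [u for u in adj[v] if dist.get(u, -2) == dist[v] - 1]
             for v in dist}
    paths = []

    def walk(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in preds[v]:
            walk(u, [v] + suffix)

    walk(t, [])
    return paths


def brute_betweenness(graph):
    """Normalized betweenness via exhaustive shortest-path enumeration."""
    nodes = sorted(graph)
    n = len(nodes)
    adj = _adjacency(graph)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    if n >= 3:
        scale = (n - 1) * (n - 2) / 2
        bc = {v: x / scale for v, x in bc.items()}
    else:
        bc = {v: 0.0 for v in nodes}
    return bc


def brute_closeness(graph):
    """Within-component closeness (k-1)/sum(distances); isolates 0."""
    adj = _adjacency(graph)
    out = {}
    for v in graph:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_degree(graph):
    return {v: len(list(graph.neighbors(v))) for v in graph}


def exact_hypergeom_tail(k, n, K, N):
    """P(X >= k) by summing the exact pmf over the tail."""
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(n, K) + 1)) / denom


def textbook_bh(pvalues):
    """Step-up adjustment: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj
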