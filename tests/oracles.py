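"""Independent brute-force oracles used by the test suite.

These are deliberately naive, pure-Python reimplementations (exact rational
arithmetic, exhaustive enumeration) kept free of the code paths they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail(k: int, a: int, b: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, b, a), by exact integer arithmetic."""
    denom = comb(N, a)
    total = sum(comb(b, i) * comb(N - b, a - i) for i in range(k, min(a, b) + 1))
    return Fraction(total, denom)


def bh_step_up(pvalues):
    """Benjamini-Hochberg adjusted p-values, coded independently.

    Sort ascending, q_i = p_i * n / rank, running minimum from the largest
    rank down, cap at 1, return in input order.
    """
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    out = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * n / rank, 1.0)
        out[i] = running
    return out


def bfs_distances(adj, source):
    """Single-source shortest-path lengths on an adjacency dict."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def paths_of_length(adj, u, v, length):
    """All simple paths from u to v with exactly `length` edges (DFS)."""
    found = []

    def dfs(node, path):
        if len(path) - 1 == length:
            if node == v:
                found.append(list(path))
            return
        for w in sorted(adj[node]):
            if w not in path:
                path.append(w)
                dfs(w, path)
                path.pop()

    dfs(u, [u])
    return found


def brute_expand(adj, seeds, max_steps, cutoff):
    """Exhaustive expansion: returns (intermediate set, edge set).

    For every seed pair at distance 2..max_steps, every shortest path whose
    non-seed interior nodes all satisfy specificity >= cutoff is admitted;
    specificity is computed against the full background.  Direct seed-seed
    edges are always included.
    """
    seed_set = set(seeds)
    spec = {
        v: len(set(adj[v]) & seed_set) / len(adj[v])
        for v in adj
        if adj[v]
    }
    intermediates = set()
    edges = set()
    for u, v in combinations(sorted(seed_set), 2):
        dist = bfs_distances(adj, u)
        if v not in dist:
            continue
        d = dist[v]
        if 2 <= d <= max_steps:
            for path in paths_of_length(adj, u, v, d):
                interior = [w for w in path[1:-1] if w not in seed_set]
                if all(spec[w] >= cutoff for w in interior):
                    intermediates.update(interior)
                    edges.update(frozenset(e) for e in zip(path, path[1:]))
    for u, v in combinations(sorted(seed_set), 2):
        if v in adj[u]:
            edges.add(frozenset((u, v)))
    return intermediates, edges
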