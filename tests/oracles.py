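"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (plain BFS, explicit path
enumeration, direct combinatorial summation) without calling the package or
networkx algorithms, so agreement is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations


def adjacency(G) -> dict:
    return {v: sorted(G.neighbors(v)) for v in G.nodes()}


def bfs_distances(adj: dict, source) -> dict:
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


def oracle_apl_eff(G) -> tuple[float | None, float]:
    """(average path length over connected pairs, global efficiency)."""
    adj = adjacency(G)
    nodes = sorted(adj)
    n = len(nodes)
    dsum, isum, pairs = 0.0, 0.0, 0
    for s in nodes:
        dist = bfs_distances(adj, s)
        for t, d in dist.items():
            if t != s:
                dsum += d
                isum += 1.0 / d
                pairs += 1
    apl = dsum / pairs if pairs else None
    eff = isum / (n * (n - 1)) if n >= 2 else 0.0
    return apl, eff


def oracle_clustering(G) -> dict:
    adj = {v: set(G.neighbors(v)) for v in G.nodes()}
    out = {}
    for v, nb in adj.items():
        k = len(nb)
        if k < 2:
            out[v] = 0.0
            continue
        tri = sum(1 for a, b in combinations(sorted(nb), 2) if b in adj[a])
        out[v] = tri / (k * (k - 1) / 2)
    return out


def _all_shortest_paths(adj, dist, s, t):
    """Enumerate every shortest s-t path by backtracking the BFS levels."""
    if t not in dist:
        return
    def walk(v, acc):
        if v == s:
            yield [s] + acc
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                yield from walk(u, [v] + acc)
    yield from walk(t, [])


def oracle_betweenness(G) -> dict:
    """Unnormalized betweenness by explicit enumeration of all shortest paths
    for every unordered pair."""
    adj = adjacency(G)
    nodes = sorted(adj)
    out = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        paths = list(_all_shortest_paths(adj, dist, s, t))
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def oracle_phi(G, k: int) -> float | None:
    deg = {v: len(list(G.neighbors(v))) for v in G.nodes()}
    S = [v for v in G.nodes() if deg[v] > k]
    if len(S) < 2:
        return None
    sset = set(S)
    e = sum(1 for u, v in G.edges() if u in sset and v in sset)
    return 2.0 * e / (len(S) * (len(S) - 1))


def oracle_kc(G, subset, b: dict | None = None) -> float:
    S = set(subset)
    if len(S) < 2:
        return 0.0
    if b is None:
        b = oracle_betweenness(G)
    total = sum(b.values())
    if total == 0:
        return 0.0
    e = sum(1 for u, v in G.edges() if u in S and v in S)
    dens = 2.0 * e / (len(S) * (len(S) - 1))
    return dens * sum(b[v] for v in S) / total


def oracle_best_kc(G) -> tuple[set, float]:
    """Exhaustive maximizer over all subsets (largest maximizer on ties)."""
    nodes = sorted(G.nodes())
    b = oracle_betweenness(G)
    best, best_score = set(), -1.0
    for r in range(2, len(nodes) + 1):
        for combo in combinations(nodes, r):
            sc = oracle_kc(G, combo, b)
            if sc > best_score + 1e-12 or (abs(sc - best_score) <= 1e-12 and r > len(best)):
                best, best_score = set(combo), sc
    return best, best_score


def oracle_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of binomial-coefficient ratios."""
    if k <= 0:
        return 1.0
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def oracle_t_test_less(sample, popmean) -> float:
    """One-sided p for H1: sample mean < popmean, by the closed-form t CDF."""
    from scipy.stats import t as tdist  # distribution function only

    n = len(sample)
    mean = sum(sample) / n
    var = sum((x - mean) ** 2 for x in sample) / (n - 1)
    tstat = (mean - popmean) / math.sqrt(var / n)
    return float(tdist.cdf(tstat, df=n - 1))
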