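"""Knotty-centrality: scoring and search for a topologically central
connective core.

The knotty centrality of a node subset S combines how densely S is wired
internally with how much of the network's routing passes through it:

    KC(S) = [2 E(S) / (|S| (|S| - 1))] * [sum_{i in S} b_i / sum_{i in V} b_i]

with b the raw shortest-path betweenness of the full graph.  KC is 0 for
|S| < 2 and when total betweenness vanishes.  The search is a deterministic
greedy hill-climb (best single add-or-remove move) restarted from pairs of
top-betweenness nodes; an exhaustive subset search is available for small
graphs and serves as the optimality oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .centrality import betweenness

EXHAUSTIVE_MAX = 12


def kc(G: nx.Graph, subset, b: dict | None = None) -> float:
    """Knotty-centrality score of ``subset``; ``b`` may supply precomputed
    raw betweenness to avoid recomputation."""
    S = set(subset)
    unknown = S - set(G.nodes())
    if unknown:
        raise ValueError(f"subset contains unknown nodes: {sorted(unknown)[:5]}")
    if len(S) < 2:
        return 0.0
    if b is None:
        b = betweenness(G)
    total_b = sum(b.values())
    if total_b == 0:
        return 0.0
    e = G.subgraph(S).number_of_edges()
    density = 2.0 * e / (len(S) * (len(S) - 1))
    share = sum(b[i] for i in S) / total_b
    return density * share


@dataclass(frozen=True)
class KnottyCentreResult:
    members: frozenset
    kc_score: float
    method: str
    seed: int = 0


def _greedy_from(G, seed_set, b, total_b, adj) -> tuple[set, float]:
    S = set(seed_set)
    e_in = G.subgraph(S).number_of_edges()
    b_sum = sum(b[i] for i in S)

    def score(n_nodes, e, bs):
        if n_nodes < 2:
            return 0.0
        return (2.0 * e / (n_nodes * (n_nodes - 1))) * (bs / total_b)

    current = score(len(S), e_in, b_sum)
    nodes = sorted(G.nodes())
    for _ in range(2 * G.number_of_nodes()):
        best_gain = 0.0
        best_move = None  # (kind, node, new_e, new_b)
        for v in nodes:
            if v in S:
                if len(S) <= 2:
                    continue
                de = sum(1 for u in adj[v] if u in S)
                cand = score(len(S) - 1, e_in - de, b_sum - b[v])
                kind = "del"
            else:
                de = sum(1 for u in adj[v] if u in S)
                cand = score(len(S) + 1, e_in + de, b_sum + b[v])
                kind = "add"
            gain = cand - current
            if gain > best_gain + 1e-15:
                best_gain = gain
                best_move = (kind, v, de)
        if best_move is None:
            break
        kind, v, de = best_move
        if kind == "add":
            S.add(v)
            e_in += de
            b_sum += b[v]
        else:
            S.remove(v)
            e_in -= de
            b_sum -= b[v]
        current = score(len(S), e_in, b_sum)
    return S, current


def find_knotty_centre(
    G: nx.Graph,
    seed: int = 0,
    use_largest_component: bool = True,
) -> KnottyCentreResult | None:
    """Greedy search for the subset maximizing KC.

    Restarts from every pair of the 5 highest-betweenness nodes (ties broken
    lexicographically); at each step applies the single node addition or
    removal that most increases KC, stopping at a local optimum; the best
    restart wins.  Deterministic (``seed`` recorded for provenance only).
    Returns ``None`` when every node has zero betweenness.
    """
    if G.number_of_nodes() < 3 or G.number_of_edges() < 2:
        return None
    if use_largest_component:
        comp = max(nx.connected_components(G), key=lambda c: (len(c), sorted(c)[0]))
        G = G.subgraph(comp).copy()
    b = betweenness(G)
    total_b = sum(b.values())
    if total_b == 0:
        return None
    adj = {v: set(G.neighbors(v)) for v in G.nodes()}
    ranked = sorted(G.nodes(), key=lambda v: (-b[v], v))[:5]
    best_set: set = set()
    best_score = -1.0
    for pair in combinations(ranked, 2):
        S, sc = _greedy_from(G, pair, b, total_b, adj)
        S, sc = _neutral_expand(G, S, sc, b, total_b, adj)
        if sc > best_score + 1e-12 or (
            abs(sc - best_score) <= 1e-12 and len(S) > len(best_set)
        ):
            best_score = sc
            best_set = S
    return KnottyCentreResult(frozenset(best_set), best_score, "heuristic", seed)


def _neutral_expand(G, S, current, b, total_b, adj) -> tuple[set, float]:
    """Add nodes whose inclusion leaves KC unchanged (larger-core tie-break)."""
    S = set(S)
    e_in = G.subgraph(S).number_of_edges()
    b_sum = sum(b[i] for i in S)
    changed = True
    while changed:
        changed = False
        for v in sorted(set(G.nodes()) - S):
            de = sum(1 for u in adj[v] if u in S)
            n2 = len(S) + 1
            cand = (2.0 * (e_in + de) / (n2 * (n2 - 1))) * ((b_sum + b[v]) / total_b)
            if cand >= current - 1e-12:
                S.add(v)
                e_in += de
                b_sum += b[v]
                current = max(current, cand)
                changed = True
    return S, current


def exhaustive_knotty_centre(G: nx.Graph) -> KnottyCentreResult | None:
    """Exact maximizer over all node subsets (bitmask enumeration); intended
    for graphs with at most ~12 nodes, where it is the oracle for the greedy."""
    nodes = sorted(G.nodes())
    n = len(nodes)
    if n < 2 or n > 20:
        raise ValueError("exhaustive search supports 2..20 nodes")
    b = betweenness(G)
    total_b = sum(b.values())
    if total_b == 0:
        return None
    index = {v: i for i, v in enumerate(nodes)}
    adj_mask = [0] * n
    for u, v in G.edges():
        adj_mask[index[u]] |= 1 << index[v]
        adj_mask[index[v]] |= 1 << index[u]
    b_arr = [b[v] for v in nodes]
    best_mask, best_score = 0, -1.0
    for mask in range(1, 1 << n):
        size = mask.bit_count()
        if size < 2:
            continue
        bs = 0.0
        e2 = 0  # each internal edge counted from both endpoints
        mm = mask
        while mm:
            i = (mm & -mm).bit_length() - 1
            e2 += (adj_mask[i] & mask).bit_count()
            bs += b_arr[i]
            mm &= mm - 1
        e = e2 // 2
        score = (2.0 * e / (size * (size - 1))) * (bs / total_b)
        # ties broken toward the larger core: a bigger subset carrying the
        # same score is the more informative connective core
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and size > best_mask.bit_count()
        ):
            best_score = score
            best_mask = mask
    members = frozenset(nodes[i] for i in range(n) if best_mask >> i & 1)
    return KnottyCentreResult(members, best_score, "exhaustive")


def overlap_fraction(a, b) -> tuple[float, float]:
    """(|a∩b|/|a|, |a∩b|/|b|); a 0 component for an empty set."""
    a, b = set(a), set(b)
    inter = len(a & b)
    return (inter / len(a) if a else 0.0, inter / len(b) if b else 0.0)
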