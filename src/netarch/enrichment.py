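"""Local over-representation analysis of node sets against GMT annotation
collections.

Per term the one-sided hypergeometric tail P(X >= k) is computed for k hits in
a query of size n against a term of size K in a background of size N
("fisher" mode); "ease" mode is the conservative DAVID variant which discounts
one hit (tail at k - 1).  p-values are Benjamini–Hochberg adjusted across
terms and reported alongside the display transform

    enrichment_score = log10(1 / p).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mcode import CollapsedNetwork


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    hits: int
    set_size: int
    term_size: int
    background_size: int
    p: float
    p_adjusted: float
    enrichment_score: float


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrichment_score(p: float) -> float:
    """log10(1/p); infinite for p == 0."""
    if p < 0 or p > 1:
        raise ValueError("p must be a probability")
    if p == 0:
        return float("inf")
    return float(np.log10(1.0 / p))


def enrich(
    query: set,
    collection: dict[str, set],
    background: set,
    mode: str = "ease",
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in every term of ``collection``.

    The query must lie inside the background; term sets are intersected with
    the background first.  Returns rows sorted by ascending p (ties broken by
    term name).
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"mode must be 'fisher' or 'ease', got {mode!r}")
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query set must be a subset of the background")
    N = len(background)
    n = len(query)
    terms, ps, rows = [], [], []
    for term in sorted(collection):
        members = set(collection[term]) & background
        K = len(members)
        k = len(query & members)
        k_eff = k - 1 if mode == "ease" else k
        p = hypergeom_tail(k_eff, N, K, n)
        terms.append((term, k, K))
        ps.append(p)
    if ps:
        p_adj = multipletests(ps, method="fdr_bh")[1]
    else:
        p_adj = []
    for (term, k, K), p, pa in zip(terms, ps, p_adj):
        rows.append(
            EnrichmentRow(
                term=term,
                hits=k,
                set_size=n,
                term_size=K,
                background_size=N,
                p=float(p),
                p_adjusted=float(max(pa, p)),
                enrichment_score=enrichment_score(float(p)),
            )
        )
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def pathway_interaction_network(
    G: nx.Graph,
    collection: dict[str, set],
    terms: list[str],
) -> CollapsedNetwork:
    """Term-level interaction network: one supernode per term (weight = member
    count within ``G``), superedge weight = number of network edges running
    between the two term sets.  An edge whose endpoints lie in both terms
    (shared members) counts once per unordered term pair."""
    missing = [t for t in terms if t not in collection]
    if missing:
        raise ValueError(f"terms absent from collection: {missing[:5]}")
    nodes = set(G.nodes())
    members = {t: frozenset(collection[t] & nodes) for t in terms}
    H = nx.Graph()
    for t in terms:
        H.add_node(t, kind="module", weight=len(members[t]))
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            a, b = members[t1], members[t2]
            w = sum(
                1
                for u, v in G.edges()
                if (u in a and v in b) or (u in b and v in a)
            )
            if w > 0:
                H.add_edge(t1, t2, weight=w)
    return CollapsedNetwork(H, dict(members))
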