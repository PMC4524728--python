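"""Node centrality battery: degree, closeness, betweenness, brokering.

Closeness uses the Wasserman–Faust within-component scaling
((n_c - 1)/(N - 1)) * ((n_c - 1)/sum of distances), so nodes in small
components are down-weighted and isolated nodes score 0.  Betweenness is the
exact Brandes shortest-path count, unnormalized.  The brokering coefficient

    b_i = (k_i / (N - 1)) * (1 - C_i)

rewards high degree combined with low local clustering — nodes that tie
together neighborhoods which are otherwise not directly connected.

z-scores are standardized over connected (degree >= 1) nodes only; a z-column
with zero variance makes the corresponding core selection empty.
"""

from __future__ import annotations

import warnings as _warnings

import networkx as nx
import numpy as np
import pandas as pd


def betweenness(G: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (each unordered pair counted once)."""
    return nx.betweenness_centrality(G, normalized=False)


def closeness(G: nx.Graph) -> dict[str, float]:
    """Wasserman–Faust scaled closeness; 0 for isolated nodes."""
    return nx.closeness_centrality(G, wf_improved=True)


def brokering(G: nx.Graph) -> dict[str, float]:
    """b_i = normalized degree x (1 - clustering)."""
    N = G.number_of_nodes()
    if N < 2:
        raise ValueError("brokering needs >= 2 nodes")
    clust = nx.clustering(G)
    return {n: (d / (N - 1)) * (1.0 - clust[n]) for n, d in G.degree()}


def centrality_table(G: nx.Graph) -> pd.DataFrame:
    """Per-node centralities with z-scores, indexed by node.

    Columns: degree, closeness, betweenness, brokering, z_degree, z_closeness,
    z_betweenness.  Isolated nodes keep raw values but NaN z-scores (they are
    excluded from the standardization population).
    """
    nodes = sorted(G.nodes())
    df = pd.DataFrame(index=pd.Index(nodes, name="node"))
    df["degree"] = pd.Series(dict(G.degree()), dtype=float)
    df["closeness"] = pd.Series(closeness(G))
    df["betweenness"] = pd.Series(betweenness(G))
    df["brokering"] = pd.Series(brokering(G)) if len(nodes) >= 2 else 0.0
    connected = df["degree"] > 0
    for col in ("degree", "closeness", "betweenness"):
        vals = df.loc[connected, col]
        sd = vals.std(ddof=0)
        z = (vals - vals.mean()) / sd if sd > 0 else pd.Series(np.nan, index=vals.index)
        df[f"z_{col}"] = z.reindex(df.index)
    return df


def central_core(table: pd.DataFrame, sd_mult: float = 3.0) -> set:
    """Nodes exceeding ``sd_mult`` standard deviations above the mean on
    degree, closeness AND betweenness simultaneously.

    Returns the empty set (with a warning) when any z-column is degenerate.
    """
    zcols = ["z_degree", "z_closeness", "z_betweenness"]
    if table[zcols].isna().all().any():
        _warnings.warn("zero-variance centrality column; central core is empty")
        return set()
    mask = (table[zcols] > sd_mult).all(axis=1)
    return set(table.index[mask])


def top_brokers(table: pd.DataFrame, n: int, exclude: set | None = None) -> list:
    """Top ``n`` nodes by brokering coefficient (descending, ties broken
    lexicographically), after removing ``exclude``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    exclude = exclude or set()
    sub = table.loc[[i for i in table.index if i not in exclude]]
    ranked = sorted(sub.index, key=lambda i: (-sub.at[i, "brokering"], i))
    return ranked[:n]
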