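"""Global topology metrics: clustering, path length, efficiency, power-law fit.

Conventions for disconnected graphs (the field's tools disagree, so they are
fixed here once): average path length is taken over connected unordered pairs
only — a ``scope="lcc"`` variant restricts to the largest connected component —
and disconnected pairs contribute 0 to global efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .errors import PowerLawFitError, UndefinedMetricError


@dataclass(frozen=True)
class GlobalMetrics:
    n_nodes: int
    n_edges: int
    avg_path_length: float
    avg_clustering: float
    global_efficiency: float
    powerlaw_exponent: float | None
    powerlaw_xmin: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def node_clustering(G: nx.Graph) -> dict[str, float]:
    """Local clustering coefficient C_i = triangles / (k_i (k_i - 1) / 2);
    0 for nodes of degree < 2."""
    return nx.clustering(G)


def average_clustering(G: nx.Graph) -> float:
    if G.number_of_nodes() == 0:
        raise UndefinedMetricError("clustering undefined on the empty graph")
    return nx.average_clustering(G)


def _pair_distance_sums(G: nx.Graph) -> tuple[float, float, int]:
    """(sum of d, sum of 1/d, number of connected ordered pairs)."""
    dist_sum = 0.0
    inv_sum = 0.0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for d in dists.values():
            if d > 0:
                dist_sum += d
                inv_sum += 1.0 / d
                pairs += 1
    return dist_sum, inv_sum, pairs


def average_path_length(G: nx.Graph, scope: str = "pairs") -> float:
    """Mean shortest-path length.

    ``scope="pairs"``: over all connected unordered pairs (disconnected pairs
    excluded); ``scope="lcc"``: over the largest connected component only.
    For a connected graph the two coincide.
    """
    if G.number_of_nodes() < 2:
        raise UndefinedMetricError("average path length needs >= 2 nodes")
    if scope == "lcc":
        comp = max(nx.connected_components(G), key=len)
        G = G.subgraph(comp)
        if G.number_of_nodes() < 2:
            raise UndefinedMetricError("largest component has no connected pair")
    elif scope != "pairs":
        raise ValueError(f"unknown scope {scope!r}")
    dist_sum, _, pairs = _pair_distance_sums(G)
    if pairs == 0:
        raise UndefinedMetricError("no connected pair of nodes")
    return dist_sum / pairs


def global_efficiency(G: nx.Graph) -> float:
    """E = mean over all ordered pairs of 1/d(i,j); disconnected pairs count 0."""
    n = G.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("global efficiency needs >= 2 nodes")
    _, inv_sum, _ = _pair_distance_sums(G)
    return inv_sum / (n * (n - 1))


def fit_power_law(degrees, method: str = "mle") -> tuple[float, int]:
    """Fit a discrete power law P(k) ~ k^-alpha to a degree sequence.

    ``method="mle"`` (default): maximum-likelihood exponent with the
    Kolmogorov–Smirnov-minimizing lower cutoff xmin (zeta-function normalized
    tail model).  ``method="regression"``: ordinary least squares on the
    log-log degree histogram with xmin = smallest positive degree, kept as a
    cruder but traditional fallback.

    Returns ``(exponent, xmin)``.  Raises :class:`PowerLawFitError` when fewer
    than 10 positive degrees or fewer than 3 distinct values are supplied.
    """
    ks = np.asarray([int(k) for k in degrees if k > 0], dtype=np.int64)
    if ks.size < 10 or np.unique(ks).size < 3:
        raise PowerLawFitError(
            f"need >= 10 positive degrees with >= 3 distinct values "
            f"(got {ks.size} positive, {np.unique(ks).size} distinct)"
        )
    if method == "regression":
        vals, counts = np.unique(ks, return_counts=True)
        slope, _ = np.polyfit(np.log(vals), np.log(counts / counts.sum()), 1)
        return float(-slope), int(vals.min())
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")

    def mle_alpha(tail: np.ndarray, xmin: int) -> float:
        logsum = np.log(tail).sum()
        n = tail.size

        def nll(alpha: float) -> float:
            return n * np.log(zeta(alpha, xmin)) + alpha * logsum

        res = minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
        return float(res.x)

    best: tuple[float, float, int] | None = None  # (ks_distance, alpha, xmin)
    candidates = np.unique(ks)
    # cap candidate xmins so the tail keeps enough mass for a stable fit
    candidates = candidates[: max(1, len(candidates) - 2)]
    for xmin in candidates:
        tail = ks[ks >= xmin]
        if tail.size < 10 or np.unique(tail).size < 2:
            continue
        alpha = mle_alpha(tail, int(xmin))
        xs = np.unique(tail)
        ecdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
        z = zeta(alpha, xmin)
        model_cdf = 1.0 - zeta(alpha, xs + 1) / z
        dist = float(np.abs(ecdf - model_cdf).max())
        if best is None or dist < best[0]:
            best = (dist, alpha, int(xmin))
    if best is None:
        raise PowerLawFitError("no viable xmin candidate")
    return best[1], best[2]


def global_metrics(G: nx.Graph, path_scope: str = "pairs") -> GlobalMetrics:
    """Bundle of the headline topology numbers for a network."""
    try:
        exponent, xmin = fit_power_law([d for _, d in G.degree()])
    except PowerLawFitError:
        exponent, xmin = None, None
    return GlobalMetrics(
        n_nodes=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        avg_path_length=average_path_length(G, scope=path_scope),
        avg_clustering=average_clustering(G),
        global_efficiency=global_efficiency(G),
        powerlaw_exponent=exponent,
        powerlaw_xmin=xmin,
    )
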