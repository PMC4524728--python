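"""Targeted-removal experiment: does deleting a specific triad of hubs hurt
the network more than deleting random triads drawn from a comparison pool?

For each metric the change is the absolute difference between the intact and
the lesioned network; the headline statistic is the ratio of the targeted
change to the mean change over random triads, with a one-sided one-sample
t-test of the random-change distribution against the targeted change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .errors import UndefinedMetricError
from .metrics import average_clustering, average_path_length, global_efficiency

DEFAULT_METRICS = ("global_efficiency", "avg_path_length", "avg_clustering")

_METRIC_FUNS = {
    "global_efficiency": global_efficiency,
    "avg_path_length": average_path_length,
    "avg_clustering": average_clustering,
}


def remove_nodes(G: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph on the complement of ``nodes``."""
    nodes = set(nodes)
    unknown = nodes - set(G.nodes())
    if unknown:
        raise ValueError(f"unknown nodes: {sorted(unknown)[:5]}")
    return G.subgraph(set(G.nodes()) - nodes).copy()


def _metric_bundle(G: nx.Graph, metrics) -> dict[str, float | None]:
    """Requested metrics in one pass (path length and efficiency share the
    all-pairs BFS); ``None`` where a metric is undefined."""
    out: dict[str, float | None] = {}
    need_paths = {"global_efficiency", "avg_path_length"} & set(metrics)
    if need_paths:
        from .metrics import _pair_distance_sums

        n = G.number_of_nodes()
        dist_sum, inv_sum, pairs = _pair_distance_sums(G) if n >= 2 else (0.0, 0.0, 0)
        if "global_efficiency" in metrics:
            out["global_efficiency"] = inv_sum / (n * (n - 1)) if n >= 2 else None
        if "avg_path_length" in metrics:
            out["avg_path_length"] = dist_sum / pairs if pairs else None
    if "avg_clustering" in metrics:
        try:
            out["avg_clustering"] = average_clustering(G)
        except UndefinedMetricError:
            out["avg_clustering"] = None
    return out


def metric_change(
    G: nx.Graph,
    nodes,
    metrics=DEFAULT_METRICS,
    baseline: dict[str, float | None] | None = None,
) -> dict[str, float | None]:
    """Absolute change |m(G) - m(G minus nodes)| per metric; ``None`` when the
    metric is undefined on the lesioned graph.  ``baseline`` may carry the
    intact network's metrics to avoid recomputation across repeated lesions."""
    bad = set(metrics) - set(_METRIC_FUNS)
    if bad:
        raise ValueError(f"unknown metrics: {sorted(bad)}")
    H = remove_nodes(G, nodes)
    if baseline is None:
        baseline = _metric_bundle(G, metrics)
    lesioned = _metric_bundle(H, metrics)
    out: dict[str, float | None] = {}
    for m in metrics:
        b, l = baseline.get(m), lesioned.get(m)
        out[m] = None if b is None or l is None else abs(b - l)
    return out


@dataclass
class PerturbationResult:
    metric_names: list[str]
    targeted_change: dict[str, float | None]
    random_changes: dict[str, list[float]]
    ratio: dict[str, float | None]
    p_value: dict[str, float | None]
    n_random: int
    seed: int
    warnings: list[str] = field(default_factory=list)


def triad_experiment(
    G: nx.Graph,
    triad,
    pool,
    n_random: int = 100,
    seed: int = 0,
    metrics=DEFAULT_METRICS,
) -> PerturbationResult:
    """Compare removal of ``triad`` against ``n_random`` random triads drawn
    from ``pool`` (triad members excluded; nodes within one draw are distinct).

    ratio(m) = targeted change / mean random change; p(m) is the one-sided
    one-sample t-test of the random changes against the targeted change
    (alternative: targeted exceeds the random mean).  Fully determined by
    ``seed``.
    """
    triad = set(triad)
    if len(triad) != 3:
        raise ValueError("triad must contain exactly 3 nodes")
    pool = sorted(set(pool) - triad)
    if len(pool) < 3:
        raise ValueError("pool must contain >= 3 nodes outside the triad")
    rng = np.random.default_rng(seed)
    baseline = _metric_bundle(G, metrics)
    targeted = metric_change(G, triad, metrics, baseline=baseline)
    random_changes: dict[str, list[float]] = {m: [] for m in metrics}
    for _ in range(n_random):
        draw = rng.choice(len(pool), size=3, replace=False)
        rnd_triad = {pool[i] for i in draw}
        ch = metric_change(G, rnd_triad, metrics, baseline=baseline)
        for m in metrics:
            if ch[m] is not None:
                random_changes[m].append(ch[m])

    ratio: dict[str, float | None] = {}
    p_value: dict[str, float | None] = {}
    warnings: list[str] = []
    for m in metrics:
        t = targeted[m]
        rc = np.array(random_changes[m])
        if t is None or rc.size == 0 or rc.mean() == 0:
            ratio[m] = None
            p_value[m] = None
            warnings.append(f"{m}: ratio undefined (missing values or zero mean change)")
            continue
        ratio[m] = float(t / rc.mean())
        if rc.size < 2 or float(rc.std()) == 0.0:
            p_value[m] = 0.0 if t > float(rc.mean()) else 1.0
            warnings.append(f"{m}: degenerate random-change distribution")
        else:
            p_value[m] = float(stats.ttest_1samp(rc, popmean=t, alternative="less").pvalue)
    return PerturbationResult(
        metric_names=list(metrics),
        targeted_change=targeted,
        random_changes={m: list(v) for m, v in random_changes.items()},
        ratio=ratio,
        p_value=p_value,
        n_random=n_random,
        seed=seed,
        warnings=warnings,
    )


def subgraph_metrics_experiment(
    G: nx.Graph,
    triad,
    pool,
    subgraph_nodes,
    n_random: int = 100,
    seed: int = 0,
    metrics=DEFAULT_METRICS,
) -> PerturbationResult:
    """Same experiment, but metrics are evaluated on the induced subgraph on
    ``subgraph_nodes`` (e.g. the rich club) rather than the whole network."""
    sub = G.subgraph(set(subgraph_nodes)).copy()
    return triad_experiment(sub, triad, set(pool) & set(sub.nodes()), n_random, seed, metrics)
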