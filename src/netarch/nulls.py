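"""Degree-preserving null models and the small-world index.

The null ensemble is the normalization baseline for the rich-club coefficient:
each member is produced by attempted double-edge swaps (rejecting self-loops
and multi-edges), which conserves every node's degree exactly.  Connectedness
is not enforced.  Member seeds are derived as ``seed + index`` so ensembles are
reproducible and could be generated in parallel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import UndefinedMetricError
from .metrics import average_clustering, average_path_length

DEFAULT_SWAPS_PER_EDGE = 10


def rewire(G: nx.Graph, swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE, seed: int = 0) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    Performs ``swaps_per_edge * |E|`` swap attempts; an attempt picks two
    distinct edges (a, b), (c, d), a random pairing, and applies it unless it
    would create a self-loop or duplicate an existing edge.  Deterministic for
    a given seed.  Graphs with < 2 edges are returned as copies.
    """
    edges = [tuple(sorted(e)) for e in G.edges()]
    m = len(edges)
    H_nodes = list(G.nodes())
    if m < 2:
        H = nx.Graph()
        H.add_nodes_from(H_nodes)
        H.add_edges_from(edges)
        return H
    edge_set = set(edges)
    rng = np.random.default_rng(seed)
    attempts = swaps_per_edge * m
    idx = rng.integers(0, m, size=(attempts, 2))
    flip = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        i, j = int(idx[t, 0]), int(idx[t, 1])
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edges[i], edges[j] = e1, e2
        edge_set.add(e1)
        edge_set.add(e2)
    H = nx.Graph()
    H.add_nodes_from(H_nodes)
    H.add_edges_from(edges)
    return H


@dataclass
class NullEnsemble:
    """A reproducible set of degree-preserving randomizations of one network."""

    members: list[nx.Graph]
    source_degree_sequence: tuple[int, ...]
    seed: int
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def make_ensemble(
    G: nx.Graph,
    n: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    model: str = "swap",
) -> NullEnsemble:
    """Build ``n`` independent random comparison networks for ``G``.

    ``model="swap"`` (default): degree-preserving double-edge-swap rewirings —
    the baseline for rich-club normalization.  ``model="er"``: size-matched
    Erdős–Rényi G(N, M) graphs with the same node and edge counts (degrees not
    preserved) — the classical baseline for the small-world index.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    degseq = tuple(sorted(d for _, d in G.degree()))
    if model == "swap":
        members = [rewire(G, swaps_per_edge=swaps_per_edge, seed=seed + i) for i in range(n)]
    elif model == "er":
        nodes = sorted(G.nodes())
        members = []
        for i in range(n):
            H = nx.gnm_random_graph(len(nodes), G.number_of_edges(), seed=seed + i)
            members.append(nx.relabel_nodes(H, dict(enumerate(nodes))))
    else:
        raise ValueError(f"unknown null model {model!r}")
    return NullEnsemble(members, degseq, seed, swaps_per_edge, params={"model": model})


def small_world_index(G: nx.Graph, ensemble: NullEnsemble) -> float:
    """Humphries–Gurney small-world index
    sigma = (C / <C_rand>) / (L / <L_rand>); sigma > 1 indicates small-world
    organization.  Path lengths use the connected-pairs convention."""
    C = average_clustering(G)
    L = average_path_length(G)
    c_rand = float(np.mean([average_clustering(H) for H in ensemble.members]))
    l_rand = float(np.mean([average_path_length(H) for H in ensemble.members]))
    if c_rand == 0:
        raise UndefinedMetricError("null ensemble has zero mean clustering")
    return (C / c_rand) / (L / l_rand)


def save_ensemble(ensemble: NullEnsemble, out_dir: str | os.PathLike) -> None:
    """Cache an ensemble as a directory of edge lists plus a JSON manifest."""
    from .io import write_edges

    os.makedirs(out_dir, exist_ok=True)
    for i, H in enumerate(ensemble.members):
        write_edges(H, os.path.join(out_dir, f"member_{i:04d}.tsv"))
    manifest = {
        "n": len(ensemble.members),
        "seed": ensemble.seed,
        "swaps_per_edge": ensemble.swaps_per_edge,
        "degree_sequence": list(ensemble.source_degree_sequence),
    }
    with open(os.path.join(out_dir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2)


def load_ensemble(out_dir: str | os.PathLike) -> NullEnsemble:
    from .io import load_scored_edges

    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    members = [
        load_scored_edges(os.path.join(out_dir, f"member_{i:04d}.tsv"), score_min=0.0)
        for i in range(manifest["n"])
    ]
    return NullEnsemble(
        members,
        tuple(manifest["degree_sequence"]),
        manifest["seed"],
        manifest["swaps_per_edge"],
    )
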