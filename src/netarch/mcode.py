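"""MCODE-style dense-module detection and module collapse.

Vertex weighting follows the molecular-complex-detection scheme: the weight of
a node is the density of the highest k-core of its closed neighborhood times
that core's order.  Complexes are then grown outward from unvisited seeds in
decreasing weight order.  A neighbor joins the growing complex when

  (a) its weight is at least (1 - node_score_cutoff) times the seed weight, and
  (b) it is adjacent to at least min(k_core, current complex size) members.

Condition (b) is this package's density-preserving growth constraint: weight
thresholding alone cannot stop a complex from leaking across a single bridge
edge between two equally dense regions (the bridge endpoints carry the same
weight as the region interiors), whereas requiring k_core-fold attachment keeps
each complex a cohesive unit and recovers planted cliques exactly.  Complexes
that do not contain a ``k_core``-core are discarded, as in the original tool;
optional haircut (iterative removal of singly-connected nodes) and fluff are
available but off by default.

Module scores are density x size.  ``collapse`` replaces each module by a
supernode and counts cross-group edges as superedge weights, which is how the
module-interaction and non-club/module networks are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = False
    fluff: bool = False


@dataclass
class ModuleSet:
    modules: list[tuple[frozenset, float]]
    params: MCODEParams = field(default_factory=MCODEParams)
    min_size_applied: int | None = None

    def __len__(self) -> int:
        return len(self.modules)

    def node_sets(self) -> list[frozenset]:
        return [m for m, _ in self.modules]


@dataclass
class CollapsedNetwork:
    """Weighted supernode graph: node attr ``weight`` = member count, edge
    attr ``weight`` = number of source edges between the two groups."""

    graph: nx.Graph
    members: dict[str, frozenset]

    def module_supernodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "module"}


def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def _highest_k_core(G: nx.Graph) -> tuple[nx.Graph, int]:
    if G.number_of_edges() == 0:
        return G, 0
    core_nums = nx.core_number(G)
    k = max(core_nums.values())
    sub = G.subgraph([v for v, c in core_nums.items() if c >= k])
    return sub, k


def mcode_weights(G: nx.Graph) -> dict[str, float]:
    """weight(v) = density of the highest k-core of v's closed neighborhood
    times that core's number; 0 for isolated nodes."""
    weights: dict[str, float] = {}
    for v in G.nodes():
        nbhd = set(G.neighbors(v)) | {v}
        if len(nbhd) == 1:
            weights[v] = 0.0
            continue
        sub = G.subgraph(nbhd)
        core, k = _highest_k_core(sub)
        weights[v] = _density(core) * k
    return weights


def mcode_find(G: nx.Graph, params: MCODEParams | None = None) -> ModuleSet:
    """Seeded-growth module detection.

    Seeds are unvisited nodes in decreasing weight order (ties broken
    lexicographically); growth is breadth-first, bounded by ``max_depth``,
    admitting neighbors that pass the weight threshold and the attachment
    constraint; every node is claimed by at most one module.
    """
    params = params or MCODEParams()
    w = mcode_weights(G)
    order = sorted(G.nodes(), key=lambda v: (-w[v], v))
    visited: set = set()
    modules: list[tuple[frozenset, float]] = []
    for seed in order:
        if seed in visited or w[seed] <= 0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * w[seed]
        complex_nodes = {seed}
        depth = {seed: 0}
        while True:  # fixpoint: attachment counts grow as the complex grows
            progressed = False
            candidates = sorted(
                {
                    v
                    for u in complex_nodes
                    for v in G.neighbors(u)
                    if v not in complex_nodes and v not in visited
                }
            )
            for v in candidates:
                if w[v] < threshold:
                    continue
                attach = sum(1 for u in G.neighbors(v) if u in complex_nodes)
                if attach < min(params.k_core, len(complex_nodes)):
                    continue
                d = min(depth[u] for u in G.neighbors(v) if u in complex_nodes) + 1
                if d > params.max_depth:
                    continue
                complex_nodes.add(v)
                depth[v] = d
                progressed = True
            if not progressed:
                break
        sub = G.subgraph(complex_nodes)
        if params.haircut:
            sub = _haircut(sub)
            complex_nodes = set(sub.nodes())
        core, k = _highest_k_core(sub)
        if k < params.k_core or len(complex_nodes) < 2:
            visited.add(seed)
            continue
        if params.fluff:
            extra = {
                v
                for u in complex_nodes
                for v in G.neighbors(u)
                if v not in visited and v not in complex_nodes and w[v] > 0
            }
            complex_nodes |= extra
            sub = G.subgraph(complex_nodes)
        visited |= complex_nodes
        score = _density(sub) * len(complex_nodes)
        modules.append((frozenset(complex_nodes), score))
    modules.sort(key=lambda ms: (-ms[1], sorted(ms[0])[0]))
    return ModuleSet(modules, params)


def _haircut(sub: nx.Graph) -> nx.Graph:
    H = nx.Graph(sub)
    while True:
        hairs = [v for v, d in H.degree() if d < 2]
        if not hairs or H.number_of_nodes() - len(hairs) < 2:
            return H
        H.remove_nodes_from(hairs)


def filter_modules(ms: ModuleSet, min_size: int) -> ModuleSet:
    """Keep modules with strictly more than ``min_size`` nodes."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    kept = [(m, s) for m, s in ms.modules if len(m) > min_size]
    return ModuleSet(kept, ms.params, min_size_applied=min_size)


def resolve_overlaps(ms: ModuleSet) -> ModuleSet:
    """Assign each node to one module: higher score wins, then lexicographic
    module order.  (mcode_find already yields disjoint modules; this guards
    module sets built elsewhere.)"""
    claimed: set = set()
    out: list[tuple[frozenset, float]] = []
    for m, s in sorted(ms.modules, key=lambda t: (-t[1], sorted(t[0])[0])):
        m2 = frozenset(m - claimed)
        if m2:
            claimed |= m2
            out.append((m2, s))
    return ModuleSet(out, ms.params, ms.min_size_applied)


def collapse(
    G: nx.Graph,
    ms: ModuleSet,
    restrict_to: set | None = None,
) -> CollapsedNetwork:
    """Collapse each module into one supernode (``M1``, ``M2``, ... in module
    order); nodes outside every module stay as singletons (when ``restrict_to``
    is given, only singletons inside it are kept).  Superedge weight counts the
    source edges between the two groups; intra-module edges are dropped."""
    ms = resolve_overlaps(ms)
    node_group: dict = {}
    members: dict[str, frozenset] = {}
    for i, (m, _) in enumerate(ms.modules, start=1):
        mid = f"M{i}"
        members[mid] = m
        for v in m:
            node_group[v] = mid
    H = nx.Graph()
    for mid, m in members.items():
        H.add_node(mid, kind="module", weight=len(m))
    for v in G.nodes():
        if v in node_group:
            continue
        if restrict_to is not None and v not in restrict_to:
            continue
        node_group[v] = v
        H.add_node(v, kind="node", weight=1)
    for u, v in G.edges():
        gu, gv = node_group.get(u), node_group.get(v)
        if gu is None or gv is None or gu == gv:
            continue
        if H.has_edge(gu, gv):
            H.edges[gu, gv]["weight"] += 1
        else:
            H.add_edge(gu, gv, weight=1)
    return CollapsedNetwork(H, members)
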