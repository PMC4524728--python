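import networkx as nx
import pytest

from netarch.mcode import (
    MCODEParams,
    ModuleSet,
    collapse,
    filter_modules,
    mcode_find,
    mcode_weights,
    resolve_overlaps,
)
from netarch.synthetic import gen_planted_modules


def _bridged_cliques(sizes, bridges):
    G = nx.Graph()
    cliques = []
    offset = 0
    for s in sizes:
        nodes = [f"q{offset + i:02d}" for i in range(s)]
        cliques.append(nodes)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                G.add_edge(u, v)
        offset += s
    for a, b in bridges:
        G.add_edge(cliques[a][0], cliques[b][0])
    return G, cliques


def test_weights_on_clique_and_star(k5, star4):
    assert set(mcode_weights(k5).values()) == {4.0}
    w = mcode_weights(star4)
    # hub's closed neighborhood is the star itself: 1-core of density 4/10
    assert w["0"] == pytest.approx(0.4)


def test_weight_zero_for_isolated_node():
    G = nx.Graph()
    G.add_node("x")
    G.add_edge("a", "b")
    assert mcode_weights(G)["x"] == 0.0


def test_two_bridged_k5s_give_two_clique_modules():
    G, cliques = _bridged_cliques([5, 5], [(0, 1)])
    ms = mcode_find(G)
    assert sorted(sorted(m) for m in ms.node_sets()) == sorted(sorted(c) for c in cliques)


def test_edgeless_graph_has_no_modules():
    G = nx.Graph()
    G.add_nodes_from("abc")
    assert len(mcode_find(G)) == 0


def test_planted_clique_communities_recovered_exactly():
    pn = gen_planted_modules(3, 6, 2, seed=42)
    ms = mcode_find(pn.network)
    assert sorted(sorted(m) for m in ms.node_sets()) == sorted(
        sorted(m) for m in pn.modules_truth
    )


def test_disjoint_clique_union_returns_the_cliques():
    G, cliques = _bridged_cliques([4, 5, 6], [])
    ms = mcode_find(G)
    assert sorted(sorted(m) for m in ms.node_sets()) == sorted(sorted(c) for c in cliques)


def test_determinism():
    pn = gen_planted_modules(4, 5, 3, seed=9)
    a = mcode_find(pn.network).modules
    b = mcode_find(pn.network).modules
    assert a == b


def test_filter_modules_strict_rule():
    ms = ModuleSet(
        [
            (frozenset(range(5)), 5.0),
            (frozenset(range(10, 14)), 4.0),
            (frozenset(range(20, 23)), 3.0),
            (frozenset(range(30, 32)), 2.0),
        ]
    )
    kept = filter_modules(ms, 3)
    assert len(kept) == 2 and kept.min_size_applied == 3
    assert len(filter_modules(ms, 0)) == 4


def test_collapse_counts_cross_edges():
    G = nx.Graph([("a", "b"), ("a", "c"), ("b", "c")])
    ms = ModuleSet([(frozenset({"a", "b"}), 1.0)])
    cn = collapse(G, ms)
    assert cn.graph.nodes["M1"]["weight"] == 2
    assert cn.graph.edges["M1", "c"]["weight"] == 2
    assert not cn.graph.has_edge("M1", "M1")


def test_collapse_conserves_cross_edge_counts():
    pn = gen_planted_modules(3, 6, 2, seed=42)
    G = pn.network
    ms = mcode_find(G)
    cn = collapse(G, ms)
    total_super = sum(d["weight"] for _, _, d in cn.graph.edges(data=True))
    intra = sum(G.subgraph(m).number_of_edges() for m in ms.node_sets())
    assert total_super + intra == G.number_of_edges()


def test_collapse_intra_module_only_graph_is_edgeless():
    G, cliques = _bridged_cliques([5], [])
    ms = ModuleSet([(frozenset(cliques[0]), 1.0)])
    cn = collapse(G, ms)
    assert cn.graph.number_of_edges() == 0


def test_collapse_restrict_to_drops_other_singletons():
    G = nx.Graph([("a", "b"), ("a", "x"), ("b", "y")])
    ms = ModuleSet([(frozenset({"a", "b"}), 1.0)])
    cn = collapse(G, ms, restrict_to={"x"})
    assert set(cn.graph.nodes()) == {"M1", "x"}


def test_overlap_resolution_prefers_higher_score():
    ms = ModuleSet([(frozenset({"a", "b", "c"}), 1.0), (frozenset({"c", "d"}), 5.0)])
    resolved = resolve_overlaps(ms)
    sets = resolved.node_sets()
    assert frozenset({"c", "d"}) in sets
    assert frozenset({"a", "b"}) in sets
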