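import networkx as nx
import numpy as np
import pytest
from scipy.stats import zipf

from netarch.errors import PowerLawFitError, UndefinedMetricError
from netarch.metrics import (
    average_clustering,
    average_path_length,
    fit_power_law,
    global_efficiency,
    global_metrics,
    node_clustering,
)
from oracles import oracle_apl_eff, oracle_clustering


def test_clustering_known_values(k5, star4):
    assert all(c == 1.0 for c in node_clustering(k5).values())
    assert node_clustering(star4)["0"] == 0.0
    G = nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")])
    cc = node_clustering(G)
    assert cc["a"] == pytest.approx(1 / 3)
    assert average_clustering(G) == pytest.approx(0.5833333333)


def test_path_length_and_efficiency_known_values(path3, k5):
    assert average_path_length(path3) == pytest.approx(4 / 3)
    assert average_path_length(nx.relabel_nodes(nx.complete_graph(4), str)) == 1.0
    assert global_efficiency(path3) == pytest.approx(5 / 6)
    assert global_efficiency(k5) == 1.0
    two_edges = nx.Graph([("a", "b"), ("c", "d")])
    assert global_efficiency(two_edges) == pytest.approx(1 / 3)
    assert average_path_length(two_edges) == 1.0  # disconnected pairs excluded


def test_no_connected_pair_is_undefined():
    G = nx.Graph()
    G.add_nodes_from("ab")
    with pytest.raises(UndefinedMetricError):
        average_path_length(G)


def test_lcc_scope_restricts_to_largest_component():
    G = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
    assert average_path_length(G, scope="lcc") == pytest.approx(4 / 3)


def test_metrics_match_bruteforce_oracle_on_battery(battery):
    for G in battery[:25]:
        apl, eff = oracle_apl_eff(G)
        if apl is not None:
            assert average_path_length(G) == pytest.approx(apl)
        assert global_efficiency(G) == pytest.approx(eff)
        impl = node_clustering(G)
        for v, c in oracle_clustering(G).items():
            assert impl[v] == pytest.approx(c)


def test_efficiency_one_iff_complete(battery):
    for G in battery[:15]:
        n = G.number_of_nodes()
        complete = G.number_of_edges() == n * (n - 1) // 2
        assert (global_efficiency(G) == pytest.approx(1.0)) == complete


def test_clustering_one_on_clique_unions():
    G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
    assert average_clustering(G) == 1.0


def test_power_law_recovers_ba_exponent():
    G = nx.barabasi_albert_graph(2000, 3, seed=11)
    alpha, xmin = fit_power_law([d for _, d in G.degree()])
    assert 2.3 <= alpha <= 3.6
    assert xmin >= 3


def test_power_law_parameter_recovery_on_zipf_sample():
    sample = zipf.rvs(2.5, size=5000, random_state=7)
    alpha, _ = fit_power_law(sample)
    assert alpha == pytest.approx(2.5, abs=0.2)


def test_power_law_degenerate_inputs_rejected():
    with pytest.raises(PowerLawFitError):
        fit_power_law([3] * 50)  # single distinct value
    with pytest.raises(PowerLawFitError):
        fit_power_law([1, 2, 3])  # too few observations


def test_power_law_regression_fallback():
    sample = zipf.rvs(2.5, size=5000, random_state=7)
    alpha, xmin = fit_power_law(sample, method="regression")
    assert xmin == 1 and 1.5 < alpha < 3.5


def test_global_metrics_bundle(k5):
    gm = global_metrics(k5)
    assert gm.n_nodes == 5 and gm.n_edges == 10
    assert gm.avg_path_length == 1.0 and gm.global_efficiency == 1.0
    assert gm.avg_clustering == 1.0
    assert gm.powerlaw_exponent is None  # degenerate degree sequence
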