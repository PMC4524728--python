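import networkx as nx
import numpy as np
import pytest

from netarch.nulls import make_ensemble, rewire
from netarch.richclub import (
    RichClubProfile,
    club_members,
    detect_regime,
    phi,
    phi_all,
    regime_significance,
    rho_profile,
)
from netarch.synthetic import gen_meta_proteome, gen_planted_club, gen_scale_free
from oracles import oracle_phi, oracle_t_test_less


def test_phi_known_values(k5, star4):
    assert phi(k5, 2) == 1.0
    assert phi(star4, 1) is None  # only the hub qualifies
    G = nx.Graph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "d"), ("c", "d"), ("d", "e")])
    assert phi(G, 1) == pytest.approx(10 / 12)


def test_phi_matches_bruteforce_on_battery(battery):
    for G in battery:
        fast = phi_all(G)
        kmax = max((d for _, d in G.degree()), default=0)
        for k in range(kmax):
            expected = oracle_phi(G, k)
            assert phi(G, k) == (pytest.approx(expected) if expected is not None else None)
            if expected is not None:
                assert fast[k] == pytest.approx(expected)


def test_rho_is_one_on_degree_rigid_complete_graph(k5):
    ens = make_ensemble(k5, n=5, seed=0)
    prof = rho_profile(k5, ens)
    assert all(prof.rho[k] == pytest.approx(1.0) for k in prof.rho)


def test_rho_profile_requires_nonempty_ensemble(k5):
    from netarch.nulls import NullEnsemble

    with pytest.raises(ValueError):
        rho_profile(k5, NullEnsemble([], (), 0))


def test_rho_self_consistency_near_one():
    G = rewire(gen_scale_free(300, 4, seed=7), swaps_per_edge=30, seed=123)
    prof = rho_profile(G, make_ensemble(G, n=50, seed=9))
    devs = [abs(prof.rho[k] - 1) for k in prof.rho if prof.n_above[k] >= 20]
    assert np.mean(devs) < 0.1


def test_detect_regime_longest_run_rule():
    prof = RichClubProfile(
        k_values=[1, 2, 3, 4, 5],
        phi={}, phi_rand_mean={}, phi_rand_sd={},
        rho={1: 0.9, 2: 1.2, 3: 1.3, 4: 1.1, 5: 0.8},
        n_above={}, e_above={},
    )
    assert detect_regime(prof) == (2, 4)
    prof.rho = {k: 0.9 for k in prof.k_values}
    assert detect_regime(prof) is None
    # tie broken toward the lowest k
    prof.rho = {1: 1.1, 2: 0.9, 3: 1.1, 4: 0.9, 5: 1.2}
    assert detect_regime(prof) == (1, 1)


def test_significance_matches_t_statistic_oracle():
    nulls = np.array([0.10, 0.12, 0.11, 0.13])
    observed = 0.30
    prof = RichClubProfile(
        k_values=[5],
        phi={5: observed}, phi_rand_mean={5: float(nulls.mean())},
        phi_rand_sd={5: float(nulls.std(ddof=1))},
        rho={5: observed / nulls.mean()},
        n_above={5: 10}, e_above={5: 3},
        null_phis={5: nulls},
    )
    p_per_k, p_pooled = regime_significance(prof, regime=(5, 5))
    expected = oracle_t_test_less(list(nulls), observed)
    assert p_per_k[5] == pytest.approx(expected)
    assert p_pooled == pytest.approx(expected)
    assert expected < 0.01


def test_significance_centered_null_is_nonsignificant():
    rng = np.random.default_rng(0)
    nulls = rng.normal(0.2, 0.01, size=200)
    prof = RichClubProfile(
        k_values=[3],
        phi={3: float(nulls.mean())}, phi_rand_mean={3: float(nulls.mean())},
        phi_rand_sd={3: float(nulls.std(ddof=1))}, rho={3: 1.0},
        n_above={3: 30}, e_above={3: 40},
        null_phis={3: nulls},
    )
    _, p = regime_significance(prof, regime=(3, 3))
    assert 0.3 < p < 0.7


def test_significance_zero_variance_branch():
    prof = RichClubProfile(
        k_values=[2, 3],
        phi={2: 0.5, 3: 0.2}, phi_rand_mean={2: 0.2, 3: 0.2},
        phi_rand_sd={2: 0.0, 3: 0.0}, rho={2: 2.5, 3: 1.0},
        n_above={2: 5, 3: 4}, e_above={2: 5, 3: 1},
        null_phis={2: np.array([0.2, 0.2, 0.2]), 3: np.array([0.2, 0.2, 0.2])},
    )
    p_per_k, _ = regime_significance(prof, regime=(2, 3))
    assert p_per_k[2] == 0.0 and p_per_k[3] == 1.0
    assert prof.warnings


def test_planted_club_detected_and_recovered():
    pn = gen_planted_club(n=200, club_size=20, p_in=0.8, p_out=0.02, seed=5)
    ens = make_ensemble(pn.network, n=50, seed=6)
    prof = rho_profile(pn.network, ens)
    regime = detect_regime(prof)
    assert regime is not None
    _, p_pooled = regime_significance(prof)
    assert p_pooled < 0.05
    members = club_members(pn.network, regime)
    assert len(members & pn.club) / len(pn.club) >= 0.9


def test_club_members_rules(star4):
    assert club_members(star4, (1, 1)) == {"0"}
    assert club_members(star4, None) == set()


def test_club_members_outrank_periphery_in_literature_frequency():
    pn = gen_planted_club(n=200, club_size=20, p_in=0.8, p_out=0.02, seed=5)
    recs = gen_meta_proteome(1, 10.5, seed=8, degrees=dict(pn.network.degree()))
    freq = {r.accession: r.frequency for r in recs}
    club_mean = np.mean([freq[v] for v in pn.club])
    peri_mean = np.mean([freq[v] for v in pn.network.nodes() if v not in pn.club])
    assert club_mean > peri_mean
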