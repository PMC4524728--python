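"""Rich-club coefficient, null normalization, regime detection, significance.

For a degree threshold k let S = {i : degree(i) > k} (strict inequality) with
N>k = |S| and E>k the number of edges inside S.  The rich-club coefficient is

    phi(k) = 2 E>k / (N>k (N>k - 1)),

undefined when fewer than two nodes qualify.  Because hubs of any network meet
each other often by chance, phi is normalized by the mean coefficient of a
degree-preserving null ensemble:

    rho(k) = phi(k) / phi_random(k),

and rho(k) > 1 over a contiguous degree range is the signature of rich-club
organization.  Significance is a per-degree one-sided one-sample t-test of the
null phi distribution against the observed value, pooled as the mean p-value
across the detected regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def phi(G: nx.Graph, k: int) -> float | None:
    """Rich-club coefficient at degree threshold ``k``; ``None`` when fewer
    than 2 nodes have degree > k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    S = [n for n, d in G.degree() if d > k]
    if len(S) < 2:
        return None
    e = G.subgraph(S).number_of_edges()
    n = len(S)
    return 2.0 * e / (n * (n - 1))


def phi_all(G: nx.Graph) -> dict[int, float]:
    """phi(k) for every k from 0 to max degree - 1 where it is defined.

    Single O(E + k_max) pass: an edge with endpoint degrees (du, dv) lies
    inside S_k exactly for k < min(du, dv), and a node of degree d belongs to
    S_k for k < d, so suffix sums of two histograms give E>k and N>k.
    """
    degrees = dict(G.degree())
    if not degrees:
        return {}
    kmax = max(degrees.values())
    if kmax == 0:
        return {}
    node_hist = np.zeros(kmax + 2, dtype=np.int64)
    for d in degrees.values():
        node_hist[d] += 1
    edge_hist = np.zeros(kmax + 2, dtype=np.int64)
    for u, v in G.edges():
        edge_hist[min(degrees[u], degrees[v])] += 1
    # n_above[k] = number of nodes with degree > k, e_above[k] likewise
    n_above = np.cumsum(node_hist[::-1])[::-1]
    e_above = np.cumsum(edge_hist[::-1])[::-1]
    out: dict[int, float] = {}
    for k in range(kmax):
        n = int(n_above[k + 1])
        if n >= 2:
            out[k] = 2.0 * int(e_above[k + 1]) / (n * (n - 1))
    return out


@dataclass
class RichClubProfile:
    k_values: list[int]
    phi: dict[int, float]
    phi_rand_mean: dict[int, float]
    phi_rand_sd: dict[int, float]
    rho: dict[int, float]
    n_above: dict[int, int]
    e_above: dict[int, int]
    null_phis: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    regime: tuple[int, int] | None = None
    p_per_k: dict[int, float] = field(default_factory=dict)
    p_pooled: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.k_values:
            rows.append(
                {
                    "k": k,
                    "phi": self.phi.get(k),
                    "phi_rand_mean": self.phi_rand_mean.get(k),
                    "phi_rand_sd": self.phi_rand_sd.get(k),
                    "rho": self.rho.get(k),
                    "n_above": self.n_above.get(k),
                    "e_above": self.e_above.get(k),
                    "p": self.p_per_k.get(k),
                }
            )
        return pd.DataFrame(rows)


def rho_profile(G: nx.Graph, ensemble) -> RichClubProfile:
    """Observed phi, null mean/sd and normalized rho at every degree threshold
    defined both in the observed network and in at least one null member."""
    if len(ensemble.members) == 0:
        raise ValueError("empty null ensemble")
    obs = phi_all(G)
    member_phis = [phi_all(H) for H in ensemble.members]

    degrees = dict(G.degree())
    deg_arr = sorted(degrees.values())
    n_above_all = {k: sum(1 for d in deg_arr if d > k) for k in obs}

    k_values, phi_m, phi_s, rho, nulls, e_above = [], {}, {}, {}, {}, {}
    for k in sorted(obs):
        vals = np.array([mp[k] for mp in member_phis if k in mp])
        if vals.size == 0:
            continue
        k_values.append(k)
        phi_m[k] = float(vals.mean())
        phi_s[k] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if phi_m[k] > 0:
            rho[k] = obs[k] / phi_m[k]
        nulls[k] = vals
        n = n_above_all[k]
        e_above[k] = round(obs[k] * n * (n - 1) / 2)
    return RichClubProfile(
        k_values=k_values,
        phi={k: obs[k] for k in k_values},
        phi_rand_mean=phi_m,
        phi_rand_sd=phi_s,
        rho=rho,
        n_above={k: n_above_all[k] for k in k_values},
        e_above=e_above,
        null_phis=nulls,
    )


_RHO_TOL = 1e-9  # rho numerically indistinguishable from rho_min is not an exceedance


def detect_regime(profile: RichClubProfile, rho_min: float = 1.0) -> tuple[int, int] | None:
    """Longest contiguous run (over the evaluated degree grid) with
    rho(k) > rho_min; ties broken toward the lowest k; ``None`` if no k
    qualifies.  Stores the result on the profile and returns it.

    At low k the null preserves phi exactly (degrees are conserved), so rho
    equals rho_min up to floating-point noise there; a small tolerance keeps
    such ties out of the regime.
    """
    best: tuple[int, int] | None = None
    best_len = 0
    run_start = None
    ks = [k for k in profile.k_values if k in profile.rho]
    for i, k in enumerate(ks):
        if profile.rho[k] > rho_min + _RHO_TOL:
            if run_start is None:
                run_start = i
            run_len = i - run_start + 1
            if run_len > best_len:
                best_len = run_len
                best = (ks[run_start], k)
        else:
            run_start = None
    profile.regime = best
    return best


def regime_significance(
    profile: RichClubProfile,
    regime: tuple[int, int] | None = None,
) -> tuple[dict[int, float], float]:
    """Per-degree one-sided t-test (does observed phi exceed the null phi
    distribution?) and the pooled mean p-value across the regime.

    Degrees with zero null variance get p = 0 when the observed value exceeds
    the constant null, 1 otherwise, with a warning recorded on the profile.
    """
    if regime is None:
        regime = profile.regime
    if regime is None:
        raise ValueError("no rich-club regime detected")
    k_lo, k_hi = regime
    p_per_k: dict[int, float] = {}
    for k in profile.k_values:
        if not k_lo <= k <= k_hi:
            continue
        nulls = profile.null_phis[k]
        observed = profile.phi[k]
        null_mean = float(nulls.mean())
        null_sd = float(np.std(nulls))
        if nulls.size < 2 or null_sd <= 1e-12 * max(abs(null_mean), 1e-12):
            p = 0.0 if observed > null_mean + 1e-9 * max(observed, null_mean) else 1.0
            profile.warnings.append(f"zero null variance at k={k}; p set to {p}")
        else:
            # small p when the null sample mean lies far below the observed phi
            p = float(stats.ttest_1samp(nulls, popmean=observed, alternative="less").pvalue)
        p_per_k[k] = p
    p_pooled = float(np.mean(list(p_per_k.values())))
    profile.p_per_k = p_per_k
    profile.p_pooled = p_pooled
    return p_per_k, p_pooled


def club_members(G: nx.Graph, regime: tuple[int, int] | None) -> set:
    """Nodes with degree above the lower regime bound; empty when no regime."""
    if regime is None:
        return set()
    k_lo = regime[0]
    return {n for n, d in G.degree() if d > k_lo}
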