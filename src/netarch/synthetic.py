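"""Synthetic networks and meta-proteome tables with planted ground truth.

These generators emulate the statistical structure a literature-curated
disease interactome is assumed to have — scale-free degrees, a densely
interconnected hub club, clique-like modules, a right-skewed literature
frequency distribution — with explicit ground truth so every detector in the
package can be tested for recovery.  All generators are deterministic given
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class PlantedNetwork:
    network: nx.Graph
    club: frozenset = frozenset()
    modules_truth: list[frozenset] = field(default_factory=list)
    triad: frozenset = frozenset()
    spec: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MetaProteomeRecord:
    accession: str
    frequency: int
    sources: tuple[str, ...]


def gen_scale_free(n: int, m: int, seed: int = 0) -> nx.Graph:
    """Preferential-attachment (Barabási–Albert) graph with string node labels;
    edge count is m(n - m) by construction."""
    if not n > m >= 1:
        raise ValueError("need n > m >= 1")
    G = nx.barabasi_albert_graph(n, m, seed=seed)
    return nx.relabel_nodes(G, {i: f"n{i:04d}" for i in G.nodes()})


def _bernoulli_pairs(rng: np.random.Generator, left: list, right: list, p: float, G: nx.Graph):
    """Add each cross pair (or within-list pair when left is right) with prob p."""
    same = left is right
    for i, u in enumerate(left):
        vs = right[i + 1 :] if same else right
        if not vs:
            continue
        mask = rng.random(len(vs)) < p
        for v, hit in zip(vs, mask):
            if hit:
                G.add_edge(u, v)


def gen_planted_club(
    n: int = 300,
    club_size: int = 30,
    p_in: float = 0.8,
    p_out: float = 0.02,
    seed: int = 0,
    p_club_periphery: float | None = None,
    triad_out: float = 0.0,
) -> PlantedNetwork:
    """Network with a planted rich club: ``club_size`` hubs wired among
    themselves with density ``p_in`` and attached to the periphery with
    probability ``p_club_periphery`` (default 5 x p_out, giving the club the
    elevated degree that makes it a degree-defined rich club), over a sparse
    periphery (Erdős–Rényi with ``p_out``).

    ``triad_out`` > 0 additionally plants a high-centrality triad: the first
    three club nodes each attach to that fraction of the periphery, making
    them dominate degree, closeness and betweenness.
    """
    if club_size >= n and not (club_size == n and p_in == 1.0):
        raise ValueError("club_size must be < n")
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out (club undetectable otherwise)")
    if p_club_periphery is None:
        p_club_periphery = min(1.0, 5.0 * p_out)
    rng = np.random.default_rng(seed)
    club = [f"club{i:03d}" for i in range(club_size)]
    periphery = [f"peri{i:04d}" for i in range(n - club_size)]
    G = nx.Graph()
    G.add_nodes_from(club)
    G.add_nodes_from(periphery)
    _bernoulli_pairs(rng, club, club, p_in, G)
    _bernoulli_pairs(rng, periphery, periphery, p_out, G)
    _bernoulli_pairs(rng, club, periphery, p_club_periphery, G)
    triad: frozenset = frozenset()
    if triad_out > 0:
        triad = frozenset(club[:3])
        for u in club[:3]:
            mask = rng.random(len(periphery)) < triad_out
            for v, hit in zip(periphery, mask):
                if hit:
                    G.add_edge(u, v)
    return PlantedNetwork(
        network=G,
        club=frozenset(club),
        triad=triad,
        spec={
            "generator": "planted_club",
            "n": n,
            "club_size": club_size,
            "p_in": p_in,
            "p_out": p_out,
            "p_club_periphery": p_club_periphery,
            "triad_out": triad_out,
            "seed": seed,
        },
    )


def gen_planted_modules(
    n_modules: int,
    clique_size: int,
    bridges: int,
    seed: int = 0,
) -> PlantedNetwork:
    """Disjoint cliques joined by ``bridges`` random inter-clique edges; the
    cliques are the module ground truth.  Bridge endpoints are sampled per
    bridge from distinct clique pairs while enough pairs remain, so no two
    bridges between the same pair of cliques share an endpoint pattern by
    construction at small bridge counts."""
    if clique_size < 4:
        raise ValueError("clique_size must be >= 4")
    if n_modules < 1 or bridges < 0:
        raise ValueError("need n_modules >= 1, bridges >= 0")
    rng = np.random.default_rng(seed)
    G = nx.Graph()
    cliques: list[list[str]] = []
    for c in range(n_modules):
        nodes = [f"c{c}n{i:02d}" for i in range(clique_size)]
        cliques.append(nodes)
        G.add_nodes_from(nodes)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                G.add_edge(u, v)
    pairs = [(a, b) for a in range(n_modules) for b in range(a + 1, n_modules)]
    chosen: list[tuple[int, int]] = []
    if pairs and bridges:
        if bridges <= len(pairs):
            idx = rng.choice(len(pairs), size=bridges, replace=False)
        else:
            idx = rng.choice(len(pairs), size=bridges, replace=True)
        chosen = [pairs[i] for i in idx]
    for a, b in chosen:
        u = cliques[a][int(rng.integers(clique_size))]
        v = cliques[b][int(rng.integers(clique_size))]
        G.add_edge(u, v)
    return PlantedNetwork(
        network=G,
        modules_truth=[frozenset(c) for c in cliques],
        spec={
            "generator": "planted_modules",
            "n_modules": n_modules,
            "clique_size": clique_size,
            "bridges": bridges,
            "seed": seed,
        },
    )


def gen_meta_proteome(
    n: int,
    mean_freq: float = 10.5,
    seed: int = 0,
    degrees: dict | None = None,
    degree_exponent: float = 0.5,
) -> list[MetaProteomeRecord]:
    """Synthetic literature-frequency table: one record per accession with a
    right-skewed (rounded-up lognormal, sigma = 1) frequency whose sample mean
    tracks ``mean_freq``, and that many distinct synthetic report IDs.

    When ``degrees`` maps accessions to network degrees, each accession's
    expected frequency is scaled by (degree / mean degree) ** degree_exponent,
    emulating hubs being better studied; accessions are then the map's keys.
    """
    if n < 1 or mean_freq <= 1:
        raise ValueError("need n >= 1 and mean_freq > 1")
    # sigma 0.8 keeps a strong right skew while the sample mean at n ~ 1000
    # stays within a few percent of the target (sigma 1 tails are wide enough
    # to miss a 10% window at unlucky draws)
    sigma = 0.8
    # E[ceil(LN)] ~ E[LN] + 1/2, so aim the continuous mean half a unit lower
    target = max(mean_freq - 0.5, 1.0)
    mu = float(np.log(target) - sigma**2 / 2.0)
    rng = np.random.default_rng(seed)
    if degrees is not None:
        accs = sorted(degrees)
        n = len(accs)
        degarr = np.array([max(degrees[a], 1) for a in accs], dtype=float)
        scale = (degarr / degarr.mean()) ** degree_exponent
    else:
        accs = [f"P{i:05d}" for i in range(n)]
        scale = np.ones(n)
    raw = rng.lognormal(mean=mu, sigma=sigma, size=n) * scale
    freqs = np.maximum(np.ceil(raw).astype(int), 1)
    records = []
    next_report = 1
    for acc, f in zip(accs, freqs):
        sources = tuple(f"R{next_report + j:07d}" for j in range(int(f)))
        next_report += int(f)
        records.append(MetaProteomeRecord(acc, int(f), sources))
    return records


def meta_proteome_frame(records: list[MetaProteomeRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "frequency": [r.frequency for r in records],
            "sources": [";".join(r.sources) for r in records],
        }
    )


def load_meta_proteome(path) -> list[MetaProteomeRecord]:
    """Read a meta-proteome TSV (accession, frequency, sources ';'-joined)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        sources = tuple(s for s in str(row.get("sources", "")).split(";") if s and s != "nan")
        freq = int(row["frequency"]) if "frequency" in df.columns else len(sources)
        records.append(MetaProteomeRecord(str(row["accession"]), freq, sources))
    return records


def meta_proteome_summary(records: list[MetaProteomeRecord]) -> dict:
    freqs = np.array([r.frequency for r in records], dtype=float)
    return {
        "n_accessions": int(len(records)),
        "mean_frequency": float(freqs.mean()),
        "skewness": float(
            ((freqs - freqs.mean()) ** 3).mean() / (freqs.std() ** 3) if freqs.std() > 0 else 0.0
        ),
    }
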