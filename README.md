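# netarch

Topology analysis of disease protein–interaction networks: rich-club
organization, knotty centres, MCODE-style modules, centrality profiling and
targeted-removal robustness.

## What it is for

Curated disease interactomes — networks of proteins reported as dysregulated
in a condition, joined by published protein–protein interactions — tend to
concentrate their biology in a small set of densely interconnected hubs.
`netarch` is a library and CLI for characterizing that architecture, for
network/systems biologists working from STRING-style scored edge lists:

- **Rich club.** For each degree threshold k, the rich-club coefficient
  φ(k) = 2 E>k / (N>k (N>k − 1)) measures how densely the nodes of degree > k
  are wired.  Since hubs meet by chance in any network, φ is normalized by a
  degree-preserving random ensemble: ρ(k) = φ(k)/φ_random(k).  A contiguous
  run of ρ(k) > 1 is the rich-club regime; significance is a per-degree
  one-sample t-test pooled across the regime.
- **Knotty centre.** The subset S maximizing
  KC(S) = density(S) × (Σ_{i∈S} b_i / Σ_i b_i), with b raw betweenness — a
  connective core defined by routing load rather than degree.  Greedy search
  with restarts, plus an exhaustive oracle for small graphs.
- **Modules.** MCODE-style k-core-weighted seeded growth, strict size
  filtering, and collapse of modules into weighted supernode networks.
- **Node profiles.** Degree / closeness / betweenness z-scores, the multi-σ
  "central core", and the brokering coefficient
  b_i = (k_i/(N−1))(1 − C_i) identifying linker nodes.
- **Perturbation.** Change in efficiency / path length / clustering after
  removing a chosen triad of nodes, as a ratio over random triads from a
  comparison pool, with significance.
- **Enrichment.** Local hypergeometric (Fisher or EASE-style) tests of node
  sets against GMT annotation collections, BH-adjusted, with the
  log10(1/p) enrichment score.
- **Synthetic benchmarks.** Generators with planted ground truth (scale-free
  graphs, planted rich clubs and central triads, clique communities,
  right-skewed literature-frequency tables) used throughout the test suite.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
from netarch import (gen_planted_club, make_ensemble, rho_profile, detect_regime,
                     regime_significance, club_members, centrality_table, central_core,
                     triad_experiment)

pn = gen_planted_club(n=300, club_size=30, p_in=0.8, p_out=0.02, seed=42, triad_out=0.5)
G = pn.network

ens = make_ensemble(G, n=200, seed=43)           # degree-preserving nulls
prof = rho_profile(G, ens)
regime = detect_regime(prof)
p_per_k, p_pooled = regime_significance(prof)
members = club_members(G, regime)
print(f"rich-club regime: k = {regime[0]}..{regime[1]}")
print(f"pooled p-value:   {p_pooled:.3g}")
print(f"club recovery:    {len(members & pn.club)}/{len(pn.club)} planted members")

core = central_core(centrality_table(G), sd_mult=3.0)
print(f"central core:     {sorted(core)}")

res = triad_experiment(G, pn.triad, pn.club - pn.triad, n_random=100, seed=44)
print(f"efficiency ratio: {res.ratio['global_efficiency']:.1f} "
      f"(p = {res.p_value['global_efficiency']:.2g})")
```

Output:

```
rich-club regime: k = 6..167
pooled p-value:   0.0014
club recovery:    30/30 planted members
central core:     ['club000', 'club001', 'club002']
efficiency ratio: 22.2 (p = 5e-229)
```

The planted 30-hub club is recovered in full inside a detected ρ > 1 regime;
the three planted super-hubs are exactly the nodes scoring > 3σ on all three
centralities; and deleting them degrades global efficiency ~22× more than
deleting random club triads.

## Command line

Each analysis is also a subcommand over edge-list TSV files
(`node1<TAB>node2[<TAB>combined_score]`, scores in [0,1] or the STRING
integer dialect):

```sh
netarch simulate club --out data --seed 42
netarch metrics   --edges data/edges.tsv --score-min 0
netarch richclub  --edges data/edges.tsv --score-min 0 --n-null 200 --seed 42
netarch centrality --edges data/edges.tsv --score-min 0 --sd-mult 3
netarch knotty    --edges data/edges.tsv --score-min 0
netarch modules   --edges data/edges.tsv --score-min 0 --min-size 3
netarch pipeline  --config run.yaml      # full analysis, one report
```

`netarch pipeline` writes a `report.json` plus TSV/GraphML artifacts and a
manifest (config, seed, input checksum) sufficient to reproduce the run.

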