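# Methods

`netarch` analyzes the topology of disease protein–interaction networks built
from scored edge lists (STRING-style exports thresholded at a combined score,
0.4 by default).  All analyses run on the simple, undirected, unweighted graph;
confidence scores are kept only as provenance.  This note records the models,
parameter choices and numerical conventions, and what the synthetic benchmarks
do and do not demonstrate.

## Global topology

For a graph with N nodes, metrics are: local clustering
C_i = 2 T_i / (k_i (k_i − 1)) (0 for k_i < 2); average path length s as the
mean shortest-path distance over **connected unordered pairs** (a `lcc` scope
restricted to the largest component is available, since published values
rarely state which convention was used); global efficiency
E = ⟨1/d_ij⟩ over all ordered pairs with 1/d = 0 for disconnected pairs.
Degree distributions are fitted with a discrete power-law maximum-likelihood
estimator: for each candidate lower cutoff x_min the exponent maximizes the
zeta-normalized likelihood, and x_min minimizes the Kolmogorov–Smirnov
distance between the tail empirical CDF and the fitted model.  A log-log
regression on the degree histogram is available as a traditional fallback but
is not the default, being statistically much weaker.

## Null models

The rich-club baseline is a degree-preserving ensemble: each member applies
`swaps_per_edge × |E|` attempted double-edge swaps (default 10 per edge),
rejecting self-loops and duplicate edges; connectedness is not enforced.
Member seeds are `seed + index`, so ensembles are exactly reproducible and
parallelizable.  A size-matched Erdős–Rényi G(N, M) ensemble is also provided;
it is the classical baseline for the small-world index
σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) (σ > 1 indicates small-world organization),
whereas the degree-preserving ensemble is the right baseline for rich-club
normalization.  Note that double-edge-swap chains mix slowly on scale-free
graphs: a graph that is itself an incompletely mixed rewiring of a structured
network will show a spurious systematic ρ > 1 against its own further-mixed
ensemble.  Self-consistency checks in the test suite therefore mix the
starting graph with 30 swaps per edge.

## Rich club

φ(k) = 2 E>k / (N>k (N>k − 1)) over nodes of degree strictly greater than k
(undefined when fewer than two qualify), computed for all k in one pass via
suffix sums of degree and min-endpoint-degree histograms.  ρ(k) = φ(k) /
mean null φ(k).  The rich-club regime is the longest contiguous run of
evaluated degrees with ρ(k) > 1 (ties resolved toward the lowest degree);
because degree preservation makes φ(k) *identical* between network and null at
thresholds below the minimum degree, exceedances within 1e-9 of the cutoff are
ignored — otherwise floating-point noise at those structurally tied degrees
would seed arbitrary regimes.  Club membership is degree > k_lo, with the
bound exposed as a flag.

Significance follows the interactome-analysis convention: per degree, a
one-sided one-sample t-test of the null φ sample against the observed value,
pooled as the arithmetic mean p across the regime.  Users should know this
test is anticonservative: it scales the null spread by 1/√n_null, so with
hundreds of nulls even a draw a fraction of one null-SD above the mean is
declared significant.  A planted club produces pooled p many orders of
magnitude below any threshold, but a *null* network can also fall below 0.1;
conclusions should rest on ρ(k) effect sizes as much as on the pooled p.
Degrees with (numerically) zero null variance get p = 0 if the observed value
exceeds the constant null and 1 otherwise, with a warning recorded.

## Centralities and the central core

Betweenness is exact Brandes accumulation, unnormalized (pair counts);
closeness uses Wasserman–Faust within-component scaling; the brokering
coefficient is b_i = (k_i/(N−1)) (1 − C_i), rewarding hubs whose neighborhoods
are not internally wired — the profile of linker nodes.  z-scores are
standardized over connected nodes only.  The "central core" is the set of
nodes above `sd_mult` standard deviations on degree, closeness and betweenness
simultaneously; the default is 3, and the threshold is configurable because
published usage varies between 2 and 3 σ for the same analysis.

## Knotty centre

KC(S) = internal edge density of S × the share of total raw betweenness
carried by S; 0 for |S| < 2 or when total betweenness vanishes (normalization
of betweenness cancels in the share).  The search is a deterministic greedy
hill-climb: restarts from every pair of the five highest-betweenness nodes,
best single add-or-remove move per step, stop at a local optimum.  Scores tie
frequently (any fully dense subset carrying the full betweenness share scores
alike), so ties break toward the **larger** core, implemented as a
score-neutral expansion pass after convergence and as an explicit tie rule in
the exhaustive bitmask search (exact up to ~12 nodes, used as the oracle).
On small random graphs the greedy reaches ≥ 90% of the exhaustive optimum and
finds the exact maximizer on the barbell fixture.  By default the search runs
on the largest connected component.

## Modules (MCODE-style)

Vertex weight = density of the highest k-core of the closed neighborhood ×
that core's number.  Complexes grow outward from unvisited seeds in
decreasing weight order; a candidate joins when (a) its weight is at least
(1 − node_score_cutoff) × seed weight, and (b) it has at least
min(k_core, |complex|) neighbors already inside.  Constraint (b) is this
package's growth rule: weight thresholding alone cannot stop a complex from
leaking across a single bridge edge between two equally dense regions,
because bridge endpoints carry exactly the interior weight; requiring
k_core-fold attachment keeps complexes cohesive and recovers planted cliques
exactly.  Complexes lacking a k_core-core are discarded; haircut and fluff
post-processing exist but default off.  Defaults: degree_cutoff 2,
node_score_cutoff 0.2, k_core 2, max_depth 100.  Module score = density ×
size; size filtering is strict (> min_size).  Collapsing replaces each module
by a supernode weighted by member count, with superedge weights counting
cross-group source edges (intra-module edges drop; cross-edge counts are
conserved exactly).

## Perturbation

Targeted triad removal is compared against `n_random` (default 100) random
triads drawn from a comparison pool (typically the rich club).  Changes are
absolute differences of efficiency, path length and clustering between intact
and lesioned graphs; the ratio is targeted change over mean random change,
with a one-sided one-sample t-test of the random-change distribution against
the targeted change.  The ratio equals 1 exactly when targeted and random
triads are related by an automorphism (e.g. consecutive triads on a cycle, or
any triads of a complete graph); mere vertex-transitivity does not suffice,
because 3-subsets of a vertex-transitive graph need not be equivalent.

## Enrichment

Over-representation uses the one-sided hypergeometric tail P(X ≥ k); "ease"
mode discounts one hit (tail at k − 1), the conservative convention of
annotation servers, and is the default.  Benjamini–Hochberg adjustment is
applied across terms; the display transform is log10(1/p).  The default
background is the analyzed network's node set.  Term-interaction networks take
one supernode per term and count each network edge once per unordered term
pair it connects, including edges inside the intersection of two terms.

## Synthetic data

The generators define the benchmark conditions:

- **Scale-free**: preferential attachment; at n = 1050, m = 21 the edge count
  m(n − m) = 21,609 matches the order of magnitude of a curated disease
  interactome.
- **Planted club**: `club_size` hubs wired at density `p_in` (default 0.8)
  over a sparse periphery (`p_out` 0.02), attached to the periphery with
  probability 5 × p_out — chosen once so the club is degree-separated from
  the periphery, which is what makes it a *rich* club rather than merely a
  dense subgraph.  With `triad_out` > 0 the first three club nodes also attach
  to that fraction of the periphery, planting a dominant central triad.
- **Planted modules**: disjoint cliques plus a small number of random
  inter-clique bridge edges, drawn between distinct clique pairs while
  possible.
- **Meta-proteome**: literature frequencies as rounded-up lognormal draws
  (σ = 0.8, median calibrated so the sample mean tracks the target, default
  10.5); σ = 0.8 keeps a strong right skew while the mean of ~1000 draws stays
  within a few percent of the target.  An optional degree-correlated mode
  scales expected frequency by (degree/mean degree)^0.5, emulating hubs being
  better studied.

These benchmarks show that the detectors recover unambiguous planted
structure at realistic sizes and that every metric agrees exactly with brute
force on small graphs.  They do not emulate several features of real curated
interactomes: STRING score distributions and their thresholding artifacts,
annotation-driven ascertainment bias (beyond the simple degree–frequency
coupling), overlapping complexes, or degree distributions with the exact
measured exponent.  Passing them therefore validates the machinery, not any
biological claim about a particular dataset.

## Problem sizes and determinism

Benchmarks run at n = 300 with 100–200 nulls and 100 random triads, sizes at
which every stage completes in seconds while keeping the planted effects
unambiguous.  Every stochastic step takes an explicit seed (ensembles derive
member seeds as seed + index); pipelines echo their configuration, seed and
input checksum into a manifest sufficient to reproduce the run bit-for-bit.
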