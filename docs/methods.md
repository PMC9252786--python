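# Methods

This note documents the models, parameters and design choices behind
`drugnet`, and what the synthetic benchmark does and does not show.

## Data model

An `Interactome` holds genes, drugs, undirected gene–gene interactions
(GGI) and bipartite drug–gene interactions (DGI). Genes carry three
annotation maps: driver-catalog membership per cancer type, somatic
mutation frequency per cancer type (a fraction in [0, 1]) and
tissue-wise expression (non-negative, TPM-like). Drugs carry four
boolean flags: regulatory approval (FDA/EMA/HC collapsed into one bit at
load time, since the flags are used jointly), ATC class L membership
(antineoplastic or immunomodulating), presence on a curated
approved-anticancer-drug list, and membership in the CTRP cell-line-tested
set. DGI edges are labelled `inhibitor`, `activator` or `other`, and a
search can be restricted to any non-empty subset of actions.

Self-loops are dropped and edges deduplicated per (pair, dataset) at
load time; dataset provenance is kept but never enters scoring — each
dataset is treated as a selectable snapshot, not a weighted ensemble.
Attribute rows naming unknown nodes are skipped with a warning because
sparse annotation coverage is the norm in this kind of data; missing
annotation values are treated as 0, not as errors.

## Edge weighting

The sources never state a weighting formula, so the package defines one
with the required monotonicity and boundedness. Let `a(g)` be the
selected annotation (mutation frequency for a cancer type, or expression
for a tissue) rescaled to [0, 1] by dividing by the interactome-wide
maximum; missing values are 0. For an edge (u, v), with
`m = (a_u + a_v)/2`:

* shortest-path cost `c = 1/(1 + m)` ∈ [1/2, 1] — paths through
  relevant genes get cheaper, never free, never negative;
* random-walk multiplier `w = 1 + m` ∈ [1, 2] — row-normalized, so the
  chain stays stochastic while preferring annotated regions.

With weighting disabled both are exactly 1, and hop counts are
recovered. Drug endpoints contribute `a = 0`.

## The drug layer is a set of sinks

Drugs "lie outside the disease module": a drug must never mediate
gene–gene connectivity. The layered drug–gene graph is therefore a
directed graph with gene↔gene edges in both directions and gene→drug
edges only. The sink contract — every gene–gene shortest path in the
layered graph equals its gene-only counterpart — holds by construction
rather than by convention, and is verified exhaustively on fixtures.

## Algorithms

**TrustRank.** Random walk with restart; restart mass uniform over the
seeds. Defaults: damping 0.85, L1 convergence tolerance 1e-6, at most
100 iterations (standard PageRank conventions; exposed as parameters).
Genes with no edges are dangling and redistribute to the restart
distribution. Drug sinks are scored by a single absorption step:
`score(D) = damping · Σ_t p(t) · w(t,D) / W(t)` over targets `t`, where
`W(t)` is t's total out-weight including drug edges. An alternative
would be to keep drugs inside the chain as dangling nodes; that was
rejected because drug edges would then dilute every target gene's
out-distribution and shift gene scores depending on which drugs are
loaded. Under absorption, gene scores are *exactly* those of the
drug-free network — the sink contract holds for scores, not only for
distances — and "receive but never forward" is literal.

**Degree / harmonic / betweenness relative to the seeds.** All three are
seed-restricted (the semantics of the precursor platforms): degree
counts edges to seed genes; harmonic sums `1/d(v, s)` over seeds with
unreachable seeds contributing 0; betweenness counts, for unordered seed
pairs only, the fraction of shortest s–t paths through v (endpoints
excluded). Betweenness is a Brandes accumulation with the dependency
initialized at seed targets, halved because each unordered pair is
visited from both endpoints. A global mode would be a trivial extension
but is not what seed-anchored tasks need.

**Multi-level Steiner tree.** The first tree is the classic
shortest-path heuristic — MST of the terminals' metric closure, expanded
to shortest paths, reduced to an MST and pruned of non-terminal
leaves — which carries the 2(1 − 1/ℓ) approximation guarantee for ℓ
terminals. Additional trees (default 5 in total) diversify the solution:
one inserts terminals in degree-descending order, the rest in
RNG-shuffled orders, each attaching the next terminal by its cheapest
path to the growing tree. Trees costlier than (1 + tolerance/100) × the
best tree are discarded (default tolerance 10%). The returned subnetwork
is the union of the kept trees (individual trees are preserved on the
result); it is gene-only, and the union of several trees is naturally
allowed to contain cycles. Seeds spanning several components trigger a
warning and the tree is built on the component holding the most seeds.

**KeyPathwayMiner-style extraction.** A greedy INES-flavored heuristic
for: maximize included seeds in a connected subnetwork with at most `k`
non-seed "exception" genes. From every seed start, the growth repeatedly
attaches the not-yet-included seed reachable through the fewest
exceptions (Dijkstra where entering a seed is free and entering a
non-seed costs one exception; ties prefer higher-degree, then
lexicographically smaller nodes), adding the connecting path, until no
remaining seed fits the leftover budget. A neighbor-at-a-time variant
was tried first and stalls whenever the nearest missing seed is two or
more exceptions away (every single neighbor has zero immediate gain);
the path-granular greedy is the same objective — cheapest new seed per
exception spent — without the stall, and empirically attains the
exhaustive optimum on all tested instances (n ≤ 14, k ≤ 2). With k = 0
and disconnected seeds it returns the largest seed-induced component.
Every exception lies on a path between included seeds by construction.

**Network proximity.** Raw closest-distance
`d(S,T) = (1/|T|) Σ_{t∈T} min_{s∈S} d(t,s)` on the gene graph. The null
replaces both S and T with degree-matched random gene sets: genes are
sorted by degree and chunked into bins of at least 100 (the trailing
short bin merges into its predecessor), and each member is replaced by a
distinct random gene from its bin. Default 100 permutations — a
desk-scale default that keeps the z-standardization stable (empirically:
decoy z mean within ±0.2, ~8% beyond |z| = 2) while staying fast; the
count is a parameter (minimum 10). One seed-replacement draw and one
multi-source Dijkstra are shared per permutation across all drugs; each
drug then draws its own target replacement, which leaves the null model
unchanged but makes the cost linear in permutations rather than
permutations × drugs. Targets outside the seed component are ignored; a
drug with no reachable target is reported unranked, as is a drug whose
null has zero spread.

**Tie-breaking** everywhere in ranked output: score descending, then
interactome degree ascending, then node id — reproducible tables, and
the degree-ascending rule prefers the more specific (less hub-like)
candidate at equal score.

## Result surfaces

Ranked tables are max-normalized (top row exactly 1 whenever any score
is positive; all-zero score maps stay 0 with a warning). Proximity ranks
by ascending z and maps it to `(z_max − z)/(z_max − z_min)` so that 1
remains "best" across algorithms. The `degree` column is always the
degree in the full interactome (GGI degree for genes, DGI degree for
drugs), never the result-subnetwork degree — the score-vs-degree
contrast is the point: high-degree nodes score well by chance.
"Indirect" drugs are those with no DGI edge to any seed; they are
excluded from drug tables unless requested, as are unapproved drugs.
Aggregation algorithms refuse drug ranking outright. Drug search
defaults to the top 15 rows.

Summary networks union ≥ 2 results over the same interactome (verified
by content hash) and count per node in how many tasks it occurred; edges
are the interactome edges induced on the union. The MST view connects an
arbitrary node subset through a minimum spanning tree of its metric
closure, expanding closure edges back to shortest paths so off-subset
genes appear only as connectors; disconnected subsets yield one tree per
component.

## Synthetic benchmark

`generate_interactome` builds a connected scale-free gene network by
preferential attachment over a path core, topped up with preferential
extra edges to hit exactly `round(n·mean_degree/2)` edges (defaults:
500 genes, mean degree 4). Mutation frequencies are Beta(1, 20)
(rare-skewed background), expression LogNormal(1, 1); optional
background drugs attach preferentially to high-degree genes. Everything
derives from one integer seed and serializes byte-identically.

`plant_module` selects a connected module by stochastic BFS (default 25
genes) and densifies it into a cohesive disease module: internal edges
are added until the internal density reaches 0.25 — each module gene
interacting with about a quarter of the module — and at least 3× the
background density. The fixed 0.25 target matters: any *connected*
25-gene set already exceeds 3× background in a sparse network, so a
relative-only target would leave the module tree-like and the planted
signal too weak for reliable recovery; 0.25 is a deliberately
recognizable module cohesion. Module genes get mutation frequencies
redrawn from Beta(5, 10) (enriched; the magnitudes are irrelevant to the
rank-based tests), 8 of them are flagged as drivers in a synthetic
catalog — these become the seeds. The planted rescue drug targets 5
*non-seed* module genes, so no edge connects it to any seed and plain
seed adjacency cannot see it. 40 decoy drugs draw target sets
degree-matched to the planted drug's targets; by default decoys avoid
the module (otherwise a draw that happens to hit module genes is
genuinely proximal and legitimately outranks the planted drug — it would
not be a decoy). For null-calibration experiments the
`decoy_exclude_module=False` flag gives unconstrained degree-matched
decoys, the exact population the permutation null resamples; the
module-excluding decoys are *expected* to sit slightly above z = 0
because the exclusion removes the best-connected candidates.

What the benchmark emulates: scale-free topology, a cohesive
mutation-enriched module, indirect rescue drugs, degree confounding.
What it does not: biological pathway structure, tissue panels,
inter-dataset disagreement, literature bias in DGI coverage, or
realistic interactome size. Passing the planted-recovery tests shows the
propagation machinery and the degree-preserving null work as designed;
it does not certify performance on real interactomes, whose module
structure is far noisier.

## Numerical choices and degenerate inputs

Shortest-path tie counting in betweenness compares path lengths with an
absolute tolerance of 1e-15; the oracle-equivalence tests therefore use
integer edge costs, where tie detection is exact. TrustRank iteration
stops on an L1 change ≤ tolerance; tests that compare against a dense
power-iteration oracle tighten it to 1e-13. Empty seed sets are legal
values but rejected at algorithm invocation. A single-node graph is a
TrustRank fixed point (score 1). All-zero score maps rank by degree
then id. Single-drug proximity results get normalized score 1. Config
round-trips are YAML; every CLI run echoes its fully resolved
configuration, and reruns from the echo are byte-identical.

## Problem sizes in the shipped checks

The test suite and the acceptance script fuzz 200 graphs (n ≤ 30) for
oracle equivalence, 60 connected graphs (n ≤ 12) against the exhaustive
Steiner optimum, 50 instances (n ≤ 14, k ≤ 2) against the exhaustive
extraction optimum, 20 fixtures × 40 decoys × 100 permutations for null
calibration, and 50 (suite) / 30 (script) generator seeds for
planted-drug recovery on the 500-gene default fixture — sizes chosen so
every exhaustive oracle remains tractable while the statistics are
stable.
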