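"""Network algorithms for drug-target prioritization and drug repurposing.

Seven algorithms consume a working graph plus a seed set:

==================  ====================  ==================
algorithm           target prioritization  drug repurposing
==================  ====================  ==================
trustrank           yes                   yes
degree              yes                   yes
harmonic            yes                   yes
betweenness         yes                   --
kpm                 yes                   --
multisteiner        yes                   --
proximity           --                    yes
==================  ====================  ==================

Betweenness, KeyPathwayMiner and the multi-level Steiner tree are
*aggregation* methods: they connect seeds through intermediate genes and
therefore cannot reach drugs, which sit outside the disease module.  The
remaining methods *propagate* outward from the seeds and can score drug
sinks.  Drug nodes receive but never forward mass in every algorithm:
gene scores are identical whether or not the drug layer is present.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .interactome import ACTIONS, DrugFilters, DrugnetError, Interactome, gene_subgraph
from .seeds import SeedSet

logger = logging.getLogger("drugnet")

#: algorithms able to rank drugs (propagation methods of the capability matrix)
DRUG_CAPABLE = frozenset({"trustrank", "degree", "harmonic", "proximity"})
#: algorithms able to rank targets (all but pure drug-repurposing proximity)
TARGET_CAPABLE = frozenset({"trustrank", "degree", "harmonic", "betweenness", "kpm", "multisteiner"})
#: aggregation methods: connect seeds, never reach drugs
AGGREGATION = frozenset({"betweenness", "kpm", "multisteiner"})

ALL_ALGORITHMS = DRUG_CAPABLE | TARGET_CAPABLE


class CapabilityError(DrugnetError):
    """An algorithm was asked for a result type it cannot produce."""


@dataclass
class ScoreMap:
    """Per-node scores produced by a propagation-style algorithm."""

    scores: dict[str, float]
    algorithm: str
    parameters: dict = field(default_factory=dict)
    seeds: frozenset[str] = frozenset()
    interactome_tag: str = ""

    def __post_init__(self) -> None:
        for n, s in self.scores.items():
            if not math.isfinite(s) or s < 0:
                raise ValueError(f"score for {n!r} not finite and non-negative: {s}")


@dataclass
class Subnetwork:
    """Node/edge set produced by an aggregation algorithm."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    algorithm: str
    parameters: dict = field(default_factory=dict)
    seeds: frozenset[str] = frozenset()
    interactome_tag: str = ""
    #: individual trees for the multi-level Steiner algorithm
    trees: list["Subnetwork"] = field(default_factory=list)
    cost: float = 0.0

    def __post_init__(self) -> None:
        self.edges = {_ekey(u, v) for u, v in self.edges}
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) endpoint outside node set")


@dataclass
class ProximityRecord:
    drug_id: str
    raw_distance: float
    null_mean: float
    null_sd: float
    z_score: float | None
    n_permutations: int


@dataclass
class ProximityResult:
    """Per-drug proximity of targets to seeds against a degree-matched null."""

    records: list[ProximityRecord]
    unranked: list[tuple[str, str]]
    parameters: dict = field(default_factory=dict)
    seeds: frozenset[str] = frozenset()
    interactome_tag: str = ""
    algorithm: str = "proximity"


def _ekey(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def _as_seed_ids(seeds: SeedSet | Iterable[str]) -> frozenset[str]:
    if isinstance(seeds, SeedSet):
        seeds.require_nonempty()
        return frozenset(seeds.genes)
    ids = frozenset(seeds)
    if not ids:
        raise DrugnetError("seed set is empty; algorithms need at least one seed gene")
    return ids


def _check_seeds_in_graph(G: nx.Graph, seed_ids: frozenset[str]) -> frozenset[str]:
    missing = seed_ids - set(G.nodes)
    if missing:
        raise DrugnetError(f"seed gene(s) not present in graph: {sorted(missing)}")
    return seed_ids


def _neighbors(G: nx.Graph | nx.DiGraph, v: str) -> set[str]:
    if G.is_directed():
        return set(G.successors(v)) | set(G.predecessors(v))
    return set(G.neighbors(v))


def _tag(G: nx.Graph) -> str:
    return G.graph.get("interactome_tag", "")


# -- TrustRank ----------------------------------------------------------------

def trustrank(
    graph: nx.Graph | nx.DiGraph,
    seeds: SeedSet | Iterable[str],
    damping: float = 0.85,
    tolerance: float = 1e-6,
    max_iter: int = 100,
) -> ScoreMap:
    """Random walk with restart whose restart mass is confined to the seeds.

    Gene scores are the stationary distribution of a damped walk over the
    gene-gene network, restarting uniformly on the seed genes; edge
    ``weight`` multipliers bias transitions and are row-normalized.
    Iteration stops when the L1 change drops to ``tolerance``.

    Drug sinks are scored by a single absorption step: a drug receives the
    damping-weighted stationary mass its target genes would divert along
    their drug-ward edges, and never forwards it.  Gene scores are thereby
    exactly those of the drug-free network.
    """
    if not 0.0 < damping < 1.0:
        raise DrugnetError(f"damping must lie in (0,1), got {damping}")
    seed_ids = _check_seeds_in_graph(graph, _as_seed_ids(seeds))

    genes = [n for n, k in graph.nodes(data="kind") if k != "drug"]
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    gene_seed_ids = seed_ids & set(gene_index)
    if not gene_seed_ids:
        raise DrugnetError("no seed is a gene node of the graph")

    # gene-gene out-weights (undirected sense; DiGraph stores both directions)
    out_w = np.zeros(n)
    rows, cols, vals = [], [], []
    seen = set()
    for u, v, data in graph.edges(data=True):
        if u not in gene_index or v not in gene_index:
            continue
        key = _ekey(u, v)
        if key in seen:
            continue
        seen.add(key)
        w = float(data.get("weight", 1.0))
        iu, iv = gene_index[u], gene_index[v]
        rows += [iv, iu]
        cols += [iu, iv]
        vals += [w, w]
        out_w[iu] += w
        out_w[iv] += w

    from scipy.sparse import csr_matrix

    A = csr_matrix((vals, (rows, cols)), shape=(n, n))  # A[v,u] = w(u,v)
    with np.errstate(divide="ignore"):
        inv_out = np.where(out_w > 0, 1.0 / np.maximum(out_w, 1e-300), 0.0)
    dangling = out_w == 0

    r = np.zeros(n)
    for s in gene_seed_ids:
        r[gene_index[s]] = 1.0 / len(gene_seed_ids)

    p = r.copy()
    for _ in range(max_iter):
        flow = A @ (p * inv_out)
        p_next = (1.0 - damping) * r + damping * (flow + p[dangling].sum() * r)
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta <= tolerance:
            break

    scores: dict[str, float] = {g: float(p[gene_index[g]]) for g in genes}

    # one-step absorption into drug sinks
    for d in (x for x, k in graph.nodes(data="kind") if k == "drug"):
        inflow = 0.0
        for t in _neighbors(graph, d):
            if t not in gene_index:
                continue
            w_td = float(_edge_data(graph, t, d).get("weight", 1.0))
            total = out_w[gene_index[t]] + _drug_out_weight(graph, t, gene_index)
            if total > 0:
                inflow += p[gene_index[t]] * w_td / total
        scores[d] = damping * inflow

    return ScoreMap(
        scores=scores,
        algorithm="trustrank",
        parameters={"damping": damping, "tolerance": tolerance, "max_iter": max_iter},
        seeds=seed_ids,
        interactome_tag=_tag(graph),
    )


def _edge_data(G: nx.Graph | nx.DiGraph, u: str, v: str) -> dict:
    if G.has_edge(u, v):
        return G[u][v]
    return G[v][u]


def _drug_out_weight(G: nx.Graph | nx.DiGraph, gene: str, gene_index: dict[str, int]) -> float:
    return sum(
        float(_edge_data(G, gene, nb).get("weight", 1.0))
        for nb in _neighbors(G, gene)
        if nb not in gene_index
    )


# -- local centralities relative to the seed set ------------------------------

def degree_to_seeds(graph: nx.Graph | nx.DiGraph, seeds: SeedSet | Iterable[str]) -> ScoreMap:
    """score(v) = number of edges between v and seed genes."""
    seed_ids = _check_seeds_in_graph(graph, _as_seed_ids(seeds))
    scores = {v: float(len(_neighbors(graph, v) & seed_ids)) for v in graph.nodes}
    return ScoreMap(scores, "degree", {}, seed_ids, _tag(graph))


def harmonic_to_seeds(graph: nx.Graph | nx.DiGraph, seeds: SeedSet | Iterable[str]) -> ScoreMap:
    """score(v) = sum over seeds s != v of 1 / d(v, s).

    Distances use the edge ``cost`` attribute (hop counts when absent);
    unreachable seeds contribute 0.  On the layered graph the distance
    from a drug to a seed runs through the drug's targets, never through
    another drug.
    """
    seed_ids = _check_seeds_in_graph(graph, _as_seed_ids(seeds))
    scores = {v: 0.0 for v in graph.nodes}
    for s in seed_ids:
        dist = nx.single_source_dijkstra_path_length(graph, s, weight=_cost_of)
        for v, d in dist.items():
            if v != s and d > 0:
                scores[v] += 1.0 / d
    return ScoreMap(scores, "harmonic", {}, seed_ids, _tag(graph))


def _cost_of(u, v, data) -> float:
    return float(data.get("cost", 1.0))


def betweenness_among_seeds(graph: nx.Graph | nx.DiGraph, seeds: SeedSet | Iterable[str]) -> ScoreMap:
    """Seed-restricted betweenness over the gene network.

    score(v) = sum over unordered seed pairs (s, t), v not in {s, t}, of
    the fraction of shortest s-t paths passing through v.  Implemented as
    a Brandes accumulation with the dependency initialized only at seed
    targets; each unordered pair is visited from both endpoints, so the
    accumulated total is halved.
    """
    seed_ids = _as_seed_ids(seeds)
    if len(seed_ids) < 2:
        raise DrugnetError("betweenness needs >= 2 seeds")
    G = gene_subgraph(graph)
    _check_seeds_in_graph(G, seed_ids)

    scores = {v: 0.0 for v in G.nodes}
    for s in seed_ids:
        order, sigma, preds = _sp_dag(G, s)
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            coeff = delta[w] + (1.0 if (w in seed_ids and w != s) else 0.0)
            for p in preds[w]:
                delta[p] += sigma[p] / sigma[w] * coeff
            if w != s:
                scores[w] += delta[w]
    for v in scores:
        scores[v] /= 2.0
    # aggregation method: drugs can never lie on gene-gene shortest paths
    return ScoreMap(scores, "betweenness", {}, seed_ids, _tag(graph))


def _sp_dag(G: nx.Graph, source: str):
    """Dijkstra shortest-path DAG: visit order, path counts, predecessors."""
    dist: dict[str, float] = {}
    sigma: dict[str, float] = {source: 1.0}
    preds: dict[str, list[str]] = {source: []}
    order: list[str] = []
    heap = [(0.0, source)]
    seen = {source: 0.0}
    while heap:
        d, v = heapq.heappop(heap)
        if v in dist:
            continue
        dist[v] = d
        order.append(v)
        for nb, data in G[v].items():
            nd = d + float(data.get("cost", 1.0))
            if nb not in seen or nd < seen[nb] - 1e-15:
                seen[nb] = nd
                heapq.heappush(heap, (nd, nb))
                sigma[nb] = sigma[v]
                preds[nb] = [v]
            elif abs(nd - seen[nb]) <= 1e-15 and nb not in dist:
                sigma[nb] = sigma.get(nb, 0.0) + sigma[v]
                preds.setdefault(nb, []).append(v)
    return order, sigma, preds


# -- multi-level Steiner tree -------------------------------------------------

def multi_steiner(
    graph: nx.Graph | nx.DiGraph,
    seeds: SeedSet | Iterable[str],
    num_trees: int = 5,
    tolerance_percent: float = 10.0,
    rng_seed: int = 0,
) -> Subnetwork:
    """Union of approximate Steiner trees over the seed terminals.

    The first tree is the classic shortest-path heuristic - an MST of the
    terminals' metric closure, expanded back to shortest paths, reduced
    to an MST of the expansion and pruned of non-terminal leaves - which
    guarantees cost <= 2(1 - 1/l) x optimum for l terminals.  Further
    trees diversify the solution by inserting terminals in randomized
    order (the second tree uses degree-descending order), each attaching
    the next terminal via its cheapest path to the growing tree.  Trees
    costlier than (1 + tolerance_percent/100) x the best tree are
    discarded.  The result is gene-only; individual kept trees are on
    ``trees``.
    """
    if num_trees < 1:
        raise DrugnetError("num_trees must be >= 1")
    seed_ids = _as_seed_ids(seeds)
    G = gene_subgraph(graph)
    _check_seeds_in_graph(G, seed_ids)

    terminals = _largest_seed_component(G, seed_ids)
    if len(terminals) < len(seed_ids):
        logger.warning(
            "seeds span multiple components; building tree on the largest "
            "seed-containing component, excluded seeds: %s",
            sorted(seed_ids - terminals),
        )
    if len(terminals) == 1:
        (t,) = terminals
        return Subnetwork({t}, set(), "multisteiner",
                          _steiner_params(num_trees, tolerance_percent, rng_seed),
                          seed_ids, _tag(graph))

    rng = np.random.default_rng(rng_seed)
    orders: list[list[str] | None] = [None]  # metric-closure MST tree
    if num_trees > 1:
        orders.append(sorted(terminals, key=lambda v: (-G.degree(v), v)))
    rest = sorted(terminals)
    for _ in range(num_trees - 2):
        orders.append(list(rng.permutation(rest)))

    built: list[Subnetwork] = []
    for order in orders:
        if order is None:
            nodes, edges, cost = _closure_mst_tree(G, set(terminals))
        else:
            nodes, edges, cost = _steiner_tree(G, order, set(terminals))
        built.append(Subnetwork(nodes, edges, "multisteiner", {}, seed_ids, _tag(graph), cost=cost))
    best = min(t.cost for t in built)
    kept, seen_trees = [], set()
    for t in built:
        sig = frozenset(t.edges)
        if t.cost <= best * (1.0 + tolerance_percent / 100.0) + 1e-12 and sig not in seen_trees:
            seen_trees.add(sig)
            kept.append(t)

    union_nodes = set().union(*(t.nodes for t in kept))
    union_edges = set().union(*(t.edges for t in kept))
    return Subnetwork(union_nodes, union_edges, "multisteiner",
                      _steiner_params(num_trees, tolerance_percent, rng_seed),
                      seed_ids, _tag(graph), trees=kept, cost=best)


def _steiner_params(num_trees, tolerance_percent, rng_seed) -> dict:
    return {"num_trees": num_trees, "tolerance_percent": tolerance_percent, "rng_seed": rng_seed}


def _largest_seed_component(G: nx.Graph, seed_ids: frozenset[str]) -> frozenset[str]:
    """Seeds inside the component holding the most seeds (ties: smallest id)."""
    best: set[str] = set()
    best_key: tuple | None = None
    for comp in nx.connected_components(G):
        present = comp & seed_ids
        if not present:
            continue
        key = (-len(present), min(present))
        if best_key is None or key < best_key:
            best_key = key
            best = present
    return frozenset(best)


def _closure_mst_tree(G: nx.Graph, terminals: set[str]):
    """Kou-Markowsky-Berman style tree: MST of the terminal metric closure."""
    dist: dict[str, dict[str, float]] = {}
    paths: dict[str, dict[str, list[str]]] = {}
    for t in sorted(terminals):
        d, p = nx.single_source_dijkstra(G, t, weight=_cost_of)
        dist[t], paths[t] = d, p
    closure = nx.Graph()
    closure.add_nodes_from(terminals)
    for i, s in enumerate(sorted(terminals)):
        for t in sorted(terminals)[i + 1:]:
            if t in dist[s]:
                closure.add_edge(s, t, cost=dist[s][t])
    nodes: set[str] = set(terminals)
    for u, v in nx.minimum_spanning_edges(closure, weight="cost", data=False):
        nodes.update(paths[u][v])
    return _reduce_to_tree(G, nodes, terminals)


def _reduce_to_tree(G: nx.Graph, nodes: set[str], terminals: set[str]):
    sub = G.subgraph(nodes)
    mst = nx.minimum_spanning_tree(sub, weight="cost")
    pruned = nx.Graph(mst)
    while True:
        leaves = [v for v in pruned.nodes if pruned.degree(v) <= 1 and v not in terminals]
        if not leaves:
            break
        pruned.remove_nodes_from(leaves)
    out_nodes = set(pruned.nodes)
    edges = {_ekey(u, v) for u, v in pruned.edges}
    cost = sum(float(G[u][v].get("cost", 1.0)) for u, v in edges)
    return out_nodes, edges, cost


def _steiner_tree(G: nx.Graph, order: list[str], terminals: set[str]):
    tree_nodes: set[str] = {order[0]}
    for t in order[1:]:
        if t in tree_nodes:
            continue
        _, path = nx.multi_source_dijkstra(G, tree_nodes, target=t, weight=_cost_of)
        tree_nodes.update(path)
    return _reduce_to_tree(G, tree_nodes, terminals)


# -- KeyPathwayMiner-style greedy extraction ----------------------------------

def keypathwayminer_greedy(
    graph: nx.Graph | nx.DiGraph,
    seeds: SeedSet | Iterable[str],
    k: int = 0,
) -> Subnetwork:
    """Connected subnetwork maximizing included seeds with <= k exceptions.

    Greedy INES-style heuristic: grow from every seed, repeatedly
    absorbing adjacent seeds for free and - while exception budget
    remains - attaching the not-yet-included seed reachable through the
    fewest exception (non-seed) genes, adding the connecting path
    (cheapest seed gained per exception spent; ties broken toward higher
    degree, then lexicographic id).  Growth stops when no remaining seed
    is reachable within the leftover budget.  The best run over all
    starts is returned (most seeds, then fewest exceptions, then the
    lexicographically smallest node set); every exception therefore lies
    on a path between included seeds.
    """
    if k < 0:
        raise DrugnetError("k must be >= 0")
    seed_ids = _as_seed_ids(seeds)
    G = gene_subgraph(graph)
    _check_seeds_in_graph(G, seed_ids)

    best: tuple | None = None
    for start in sorted(seed_ids):
        nodes = _kpm_grow(G, seed_ids, start, k)
        n_seeds = len(nodes & seed_ids)
        n_exc = len(nodes - seed_ids)
        key = (-n_seeds, n_exc, tuple(sorted(nodes)))
        if best is None or key < best[0]:
            best = (key, nodes)
    nodes = best[1]
    edges = {_ekey(u, v) for u, v in G.subgraph(nodes).edges}
    return Subnetwork(nodes, edges, "kpm", {"k": k}, seed_ids, _tag(graph))


def _kpm_grow(G: nx.Graph, seed_ids: frozenset[str], start: str, k: int) -> set[str]:
    nodes = {start}
    used = 0
    while True:
        target, path = _cheapest_missing_seed(G, nodes, seed_ids, k - used)
        if target is None:
            return nodes
        exceptions = [v for v in path if v not in seed_ids]
        nodes.update(path)
        used += len(exceptions)


def _cheapest_missing_seed(G: nx.Graph, nodes: set[str], seed_ids: frozenset[str], budget: int):
    """Nearest not-yet-included seed by exception count, with its path.

    Dijkstra where entering a seed is free and entering a non-seed costs
    one exception; ties prefer higher-degree, lexicographically smaller
    entry nodes so growth is deterministic.
    """
    dist: dict[str, int] = {}
    prev: dict[str, str | None] = {}
    heap: list[tuple[int, int, str, str | None]] = []
    for v in sorted(nodes):
        heapq.heappush(heap, (0, 0, v, None))
    while heap:
        d, _, v, parent = heapq.heappop(heap)
        if v in dist:
            continue
        dist[v] = d
        prev[v] = parent
        if v in seed_ids and v not in nodes:
            path = []
            cur: str | None = v
            while cur is not None and cur not in nodes:
                path.append(cur)
                cur = prev[cur]
            return v, path
        for nb in G[v]:
            if nb in dist:
                continue
            step = 0 if nb in seed_ids else 1
            nd = d + step
            if nd <= budget:
                heapq.heappush(heap, (nd, -G.degree(nb), nb, v))
    return None, None


# -- network proximity --------------------------------------------------------

def network_proximity(
    graph: nx.Graph | nx.DiGraph,
    seeds: SeedSet | Iterable[str],
    interactome: Interactome,
    action_filter: Iterable[str] = ACTIONS,
    drug_filters: DrugFilters | None = None,
    n_permutations: int = 100,
    rng_seed: int = 0,
    min_bin_size: int = 100,
) -> ProximityResult:
    """Closest-distance proximity of drug targets to seeds with a z-score null.

    For each drug passing the filters, the raw proximity is
    ``d(S, T) = (1/|T|) sum_{t in T} min_{s in S} d(t, s)`` over the gene
    network.  The null replaces both S and T by degree-matched random gene
    sets (genes sorted by degree and chunked into bins of at least
    ``min_bin_size``; the trailing short bin merges into its predecessor);
    ``z = (d - mu) / sigma`` over ``n_permutations`` draws, and drugs are
    ranked by ascending z.  Targets outside the seed component are
    ignored; a drug with no target in the seed component is reported
    unranked.
    """
    if n_permutations < 10:
        raise DrugnetError("n_permutations must be >= 10")
    seed_ids = _as_seed_ids(seeds)
    G = gene_subgraph(graph)
    _check_seeds_in_graph(G, seed_ids)
    actions = set(action_filter)
    if not actions:
        raise DrugnetError("action_filter must allow at least one action")
    drug_filters = drug_filters or DrugFilters()
    rng = np.random.default_rng(rng_seed)

    dS = nx.multi_source_dijkstra_path_length(G, set(seed_ids), weight=_cost_of)
    bins, bin_of = _degree_bins(G, min_bin_size)

    candidates: list[tuple[str, list[str]]] = []
    unranked: list[tuple[str, str]] = []
    for did in sorted(interactome.drugs):
        if not drug_filters.admits(interactome.drugs[did]):
            continue
        targets = sorted(t for t in interactome.drug_targets(did, actions) if t in G)
        if not targets:
            continue
        reachable = [t for t in targets if t in dS]
        if not reachable:
            unranked.append((did, "no target in the seed component"))
            continue
        candidates.append((did, reachable))

    raw = {did: float(np.mean([dS[t] for t in ts])) for did, ts in candidates}

    # shared null: one degree-matched seed replacement + one Dijkstra sweep
    # per permutation, then per-drug degree-matched target replacement
    null: dict[str, list[float]] = {did: [] for did, _ in candidates}
    seed_list = sorted(seed_ids)
    for _ in range(n_permutations):
        s_rand = _degree_matched_sample(seed_list, bins, bin_of, rng)
        dR = nx.multi_source_dijkstra_path_length(G, set(s_rand), weight=_cost_of)
        for did, targets in candidates:
            t_rand = _degree_matched_sample(targets, bins, bin_of, rng)
            ds = [dR[t] for t in t_rand if t in dR]
            if len(ds) == len(t_rand):
                null[did].append(float(np.mean(ds)))

    records = []
    for did, _ in candidates:
        draws = np.asarray(null[did])
        if len(draws) < 2:
            unranked.append((did, "degenerate null (unreachable permutation draws)"))
            continue
        mu = float(draws.mean())
        sd = float(draws.std(ddof=1))
        if sd == 0.0:
            unranked.append((did, "null distribution has zero spread"))
            continue
        records.append(ProximityRecord(did, raw[did], mu, sd, (raw[did] - mu) / sd, len(draws)))
    records.sort(key=lambda r: (r.z_score, r.drug_id))

    return ProximityResult(
        records=records,
        unranked=unranked,
        parameters={"n_permutations": n_permutations, "rng_seed": rng_seed,
                    "action_filter": sorted(actions), "min_bin_size": min_bin_size,
                    "drug_filters": vars(drug_filters) if hasattr(drug_filters, "__dict__")
                    else drug_filters.__dict__},
        seeds=seed_ids,
        interactome_tag=_tag(graph),
    )


def _degree_bins(G: nx.Graph, min_bin_size: int):
    """Genes sorted by degree, chunked into bins of >= min_bin_size."""
    ordered = sorted(G.nodes, key=lambda v: (G.degree(v), v))
    bins: list[list[str]] = []
    for i in range(0, len(ordered), min_bin_size):
        bins.append(ordered[i:i + min_bin_size])
    if len(bins) > 1 and len(bins[-1]) < min_bin_size:
        bins[-2].extend(bins.pop())
    bin_of = {}
    for bi, members in enumerate(bins):
        for v in members:
            bin_of[v] = bi
    return bins, bin_of


def _degree_matched_sample(nodes: list[str], bins, bin_of, rng: np.random.Generator) -> list[str]:
    """Random distinct genes, one per input node, drawn from its degree bin."""
    chosen: list[str] = []
    taken: set[str] = set()
    for v in nodes:
        pool = bins[bin_of[v]]
        pick = pool[int(rng.integers(len(pool)))]
        tries = 0
        while pick in taken and tries < 50:
            pick = pool[int(rng.integers(len(pool)))]
            tries += 1
        if pick in taken:  # tiny bin: fall back to any untaken gene in the bin
            remaining = [x for x in pool if x not in taken]
            pick = remaining[int(rng.integers(len(remaining)))] if remaining else v
        taken.add(pick)
        chosen.append(pick)
    return chosen


# -- dispatch -----------------------------------------------------------------

def run_algorithm(name: str, graph, seeds, **params):
    """Run one of the seven algorithms by name."""
    name = name.lower()
    if name == "trustrank":
        return trustrank(graph, seeds, **params)
    if name == "degree":
        return degree_to_seeds(graph, seeds, **params)
    if name == "harmonic":
        return harmonic_to_seeds(graph, seeds, **params)
    if name == "betweenness":
        return betweenness_among_seeds(graph, seeds, **params)
    if name == "multisteiner":
        return multi_steiner(graph, seeds, **params)
    if name == "kpm":
        return keypathwayminer_greedy(graph, seeds, **params)
    if name == "proximity":
        return network_proximity(graph, seeds, **params)
    raise DrugnetError(f"unknown algorithm {name!r}; expected one of {sorted(ALL_ALGORITHMS)}")
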