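"""Synthetic annotated interactomes with planted disease modules.

The generator emulates the topology the algorithms are designed for: a
connected scale-free gene network (preferential attachment) with a
bipartite drug layer attached preferentially to hub genes, plus
mutation-frequency and expression annotations.  :func:`plant_module`
then plants a densified disease module, elevates its mutation
frequencies, flags a subset of module genes as cancer drivers (the seed
candidates) and adds one "rescuing" drug targeting non-seed module genes
together with degree-matched decoy drugs.  Because the planted drug
never touches a seed directly, recovering it requires genuine network
propagation - the benchmark for the whole pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .interactome import (
    Drug,
    DrugGeneInteraction,
    DrugnetError,
    Gene,
    GeneInteraction,
    Interactome,
)

logger = logging.getLogger("drugnet")

CANCER_TYPE = "synthetic_cancer"
TISSUE = "synthetic_tissue"
DRIVER_CATALOG = "synthetic_catalog"

# annotation distributions: rare-skewed background vs enriched module
BACKGROUND_MUTATION_BETA = (1.0, 20.0)
MODULE_MUTATION_BETA = (5.0, 10.0)
EXPRESSION_LOGNORMAL = (1.0, 1.0)


@dataclass
class SyntheticGroundTruth:
    """What was planted, for benchmarking recovery."""

    module_genes: set[str]
    seed_genes: set[str]
    planted_drug: str
    decoy_drugs: set[str]
    parameters: dict = field(default_factory=dict)

    def validate(self, interactome: Interactome) -> None:
        if not self.seed_genes <= self.module_genes:
            raise ValueError("seed genes must be a subset of the module")
        targets = interactome.drug_targets(self.planted_drug)
        if not targets <= self.module_genes:
            raise ValueError("planted drug targets must lie inside the module")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "seed_genes": sorted(self.seed_genes),
            "planted_drug": self.planted_drug,
            "decoy_drugs": sorted(self.decoy_drugs),
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            module_genes=set(data["module_genes"]),
            seed_genes=set(data["seed_genes"]),
            planted_drug=data["planted_drug"],
            decoy_drugs=set(data["decoy_drugs"]),
            parameters=data.get("parameters", {}),
        )


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _drug_id(i: int) -> str:
    return f"D{i:04d}"


def generate_interactome(
    n_genes: int = 500,
    mean_degree: float = 4.0,
    n_drugs: int = 0,
    targets_per_drug: int | tuple[int, int] = 3,
    rng_seed: int = 0,
) -> Interactome:
    """Connected scale-free gene network with an optional drug layer.

    Preferential attachment over a path core, topped up with preferential
    extra edges so the edge count equals ``round(n_genes * mean_degree / 2)``
    exactly.  Drugs attach to genes with probability proportional to gene
    degree; per-drug target counts are ``targets_per_drug`` (an int, or an
    inclusive (low, high) range sampled uniformly).  Mutation frequencies
    are Beta(1, 20), expression values LogNormal(1, 1).  Fully
    reproducible from ``rng_seed``.
    """
    if n_genes < 10:
        raise DrugnetError("n_genes must be >= 10")
    if mean_degree >= n_genes:
        raise DrugnetError("mean_degree must be smaller than n_genes")
    if mean_degree < 2:
        raise DrugnetError("mean_degree must be >= 2 to keep the network connected")
    rng = np.random.default_rng(rng_seed)
    target_edges = int(round(n_genes * mean_degree / 2.0))

    m = max(1, int(mean_degree // 2))
    ids = [_gene_id(i) for i in range(n_genes)]
    edges: set[tuple[int, int]] = set()
    # endpoint multiset drives preferential attachment
    endpoints: list[int] = []

    def add_edge(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in edges:
            return False
        edges.add(key)
        endpoints.extend(key)
        return True

    core = m + 1
    for i in range(1, core):
        add_edge(i - 1, i)
    for i in range(core, n_genes):
        attached = 0
        while attached < min(m, i):
            j = int(endpoints[rng.integers(len(endpoints))])
            if add_edge(i, j):
                attached += 1
    while len(edges) < target_edges:
        u = int(endpoints[rng.integers(len(endpoints))])
        v = int(endpoints[rng.integers(len(endpoints))])
        add_edge(u, v)

    mut = rng.beta(*BACKGROUND_MUTATION_BETA, size=n_genes)
    expr = rng.lognormal(*EXPRESSION_LOGNORMAL, size=n_genes)
    genes = [
        Gene(ids[i], symbol=f"SYN{i}",
             mutation_frequency={CANCER_TYPE: float(mut[i])},
             expression={TISSUE: float(expr[i])})
        for i in range(n_genes)
    ]
    ggi = [GeneInteraction(ids[u], ids[v], "synthetic") for u, v in sorted(edges)]

    drugs: list[Drug] = []
    dgi: list[DrugGeneInteraction] = []
    degree = np.zeros(n_genes)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    pdeg = degree / degree.sum()
    for di in range(n_drugs):
        did = _drug_id(di)
        k = _draw_count(targets_per_drug, rng)
        targets = rng.choice(n_genes, size=min(k, n_genes), replace=False, p=pdeg)
        drugs.append(Drug(did, name=f"drug-{di}",
                          approved=bool(rng.random() < 0.5),
                          atc_l=bool(rng.random() < 0.3),
                          cancerx=bool(rng.random() < 0.2),
                          ctrp=bool(rng.random() < 0.3)))
        for t in sorted(int(t) for t in targets):
            action = ("inhibitor", "activator", "other")[int(rng.integers(3))]
            dgi.append(DrugGeneInteraction(did, ids[t], action, "synthetic"))

    return Interactome(genes=genes, drugs=drugs, ggi=ggi, dgi=dgi)


def _draw_count(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    low, high = spec
    return int(rng.integers(low, high + 1))


def plant_module(
    interactome: Interactome,
    module_size: int = 25,
    n_seeds: int = 8,
    planted_targets: int = 5,
    n_decoys: int = 40,
    rng_seed: int = 0,
    density_factor: float = 3.0,
    internal_density: float = 0.25,
    decoy_exclude_module: bool = True,
) -> tuple[Interactome, SyntheticGroundTruth]:
    """Plant a disease module and a ground-truth rescuing drug.

    A connected gene set of ``module_size`` is selected by random
    breadth-first growth and densified into a cohesive disease module:
    edges are added until the internal edge density reaches
    ``internal_density`` (default 0.25, i.e. every module gene interacts
    with about a quarter of the module) and at least ``density_factor``
    times the background density, whichever is larger.  Module
    genes get mutation frequencies redrawn from the enriched Beta(5, 10);
    ``n_seeds`` of them are flagged as drivers.  The planted drug targets
    ``planted_targets`` *non-seed* module genes, so it never touches a
    seed directly; ``n_decoys`` decoys draw degree-matched random target
    sets, kept outside the module by default so they are genuine decoys
    (``decoy_exclude_module=False`` lifts that constraint for null-model
    calibration experiments).  Returns a new interactome plus the ground
    truth.
    """
    n_genes = len(interactome.genes)
    if module_size > n_genes / 5:
        raise DrugnetError("module_size must be at most n_genes / 5")
    if n_seeds >= module_size:
        raise DrugnetError("n_seeds must be smaller than module_size")
    if planted_targets > module_size - n_seeds:
        raise DrugnetError("planted_targets cannot exceed the non-seed module genes")
    rng = np.random.default_rng(rng_seed)

    G = nx.Graph()
    G.add_nodes_from(interactome.genes)
    G.add_edges_from((e.gene_a, e.gene_b) for e in interactome.ggi)

    module = _connected_sample(G, module_size, rng)
    module_list = sorted(module)

    # densify until internal density >= density_factor x (post-densification)
    # background density; added edges count toward the background too
    max_internal = module_size * (module_size - 1) / 2
    pair_total = n_genes * (n_genes - 1) / 2
    internal = {e for e in G.subgraph(module).edges}
    new_edges: list[tuple[str, str]] = []
    candidates = [
        (a, b)
        for i, a in enumerate(module_list)
        for b in module_list[i + 1:]
        if not G.has_edge(a, b)
    ]
    rng.shuffle(candidates)
    for a, b in candidates:
        n_int = len(internal) + len(new_edges)
        background = (G.number_of_edges() + len(new_edges)) / pair_total
        target = max(internal_density, density_factor * background)
        if n_int / max_internal >= target:
            break
        new_edges.append((a, b))

    seeds = set(rng.choice(module_list, size=n_seeds, replace=False).tolist())
    non_seed_module = sorted(module - seeds)
    planted = sorted(rng.choice(non_seed_module, size=planted_targets, replace=False).tolist())

    genes = []
    for gid, g in interactome.genes.items():
        mut = dict(g.mutation_frequency)
        drivers = {k: set(v) for k, v in g.driver_sources.items()}
        if gid in module:
            mut[CANCER_TYPE] = float(rng.beta(*MODULE_MUTATION_BETA))
        if gid in seeds:
            drivers.setdefault(CANCER_TYPE, set()).add(DRIVER_CATALOG)
        genes.append(Gene(gid, g.symbol, drivers, mut, dict(g.expression)))

    ggi = list(interactome.ggi) + [GeneInteraction(a, b, "planted") for a, b in new_edges]

    # degree-matched decoys: sample each decoy target from the planted
    # target's degree bin of the densified network
    H = nx.Graph()
    H.add_nodes_from(interactome.genes)
    H.add_edges_from((e.gene_a, e.gene_b) for e in ggi)
    bins, bin_of = _simple_degree_bins(H, min_bin_size=max(20, n_genes // 10))

    existing = len(interactome.drugs)
    planted_id = _drug_id(existing)
    drugs = list(interactome.drugs.values()) + [
        Drug(planted_id, name="planted-rescue", approved=True, atc_l=True,
             cancerx=True, ctrp=True)
    ]
    dgi = list(interactome.dgi) + [
        DrugGeneInteraction(planted_id, t, "inhibitor", "planted") for t in planted
    ]
    decoys: set[str] = set()
    for i in range(n_decoys):
        did = _drug_id(existing + 1 + i)
        decoys.add(did)
        drugs.append(Drug(did, name=f"decoy-{i}", approved=True,
                          atc_l=bool(rng.random() < 0.3),
                          cancerx=False, ctrp=bool(rng.random() < 0.3)))
        chosen: set[str] = set()
        for t in planted:
            pool = bins[bin_of[t]]
            pick = pool[int(rng.integers(len(pool)))]
            tries = 0
            while (pick in chosen or (decoy_exclude_module and pick in module)) \
                    and tries < 100:
                pick = pool[int(rng.integers(len(pool)))]
                tries += 1
            chosen.add(pick)
        for t in sorted(chosen):
            dgi.append(DrugGeneInteraction(did, t, "inhibitor", "planted"))

    out = Interactome(genes=genes, drugs=drugs, ggi=ggi, dgi=dgi)
    truth = SyntheticGroundTruth(
        module_genes=set(module),
        seed_genes=seeds,
        planted_drug=planted_id,
        decoy_drugs=decoys,
        parameters={
            "module_size": module_size, "n_seeds": n_seeds,
            "planted_targets": planted_targets, "n_decoys": n_decoys,
            "rng_seed": rng_seed, "density_factor": density_factor,
            "internal_density": internal_density,
            "decoy_exclude_module": decoy_exclude_module,
        },
    )
    truth.validate(out)
    return out, truth


def _connected_sample(G: nx.Graph, size: int, rng: np.random.Generator, retries: int = 50) -> set[str]:
    """Random connected gene set grown by stochastic BFS."""
    nodes = sorted(G.nodes)
    for _ in range(retries):
        start = nodes[int(rng.integers(len(nodes)))]
        selected = {start}
        frontier = sorted(G[start])
        while frontier and len(selected) < size:
            nxt = frontier.pop(int(rng.integers(len(frontier))))
            if nxt in selected:
                continue
            selected.add(nxt)
            frontier.extend(n for n in G[nxt] if n not in selected)
        if len(selected) == size:
            return selected
    raise DrugnetError(f"could not find a connected gene set of size {size}")


def _simple_degree_bins(G: nx.Graph, min_bin_size: int):
    ordered = sorted(G.nodes, key=lambda v: (G.degree(v), v))
    bins = [ordered[i:i + min_bin_size] for i in range(0, len(ordered), min_bin_size)]
    if len(bins) > 1 and len(bins[-1]) < min_bin_size:
        bins[-2].extend(bins.pop())
    bin_of = {v: bi for bi, members in enumerate(bins) for v in members}
    return bins, bin_of


def module_density(interactome: Interactome, module: set[str]) -> tuple[float, float]:
    """(internal density of the module, background density of the network)."""
    G = nx.Graph()
    G.add_nodes_from(interactome.genes)
    G.add_edges_from((e.gene_a, e.gene_b) for e in interactome.ggi)
    n = G.number_of_nodes()
    background = 2.0 * G.number_of_edges() / (n * (n - 1))
    sub = G.subgraph(module)
    m = len(module)
    internal = 2.0 * sub.number_of_edges() / (m * (m - 1)) if m > 1 else 0.0
    return internal, background
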