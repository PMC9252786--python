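"""Result surfaces: normalized ranked tables, summary networks, MST view.

Scores are contrasted with node degree in the full interactome: a
high-degree node is likely to be selected by chance, whereas a low-degree
node with a high score is more likely to be disease-specific.  Ranked
tables are max-normalized so the top row scores 1, mirror the drug-table
column order (name, approved, atc_l, cancerx, score, degree) and apply a
global tie-break (score descending, then degree ascending, then node id).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .algorithms import (
    AGGREGATION,
    DRUG_CAPABLE,
    ProximityResult,
    ScoreMap,
    Subnetwork,
    CapabilityError,
    _cost_of,
    _ekey,
)
from .interactome import Interactome
from .seeds import SeedSet

logger = logging.getLogger("drugnet")

_COLUMNS = ["node_id", "name", "kind", "raw_score", "normalized_score", "degree",
            "is_seed", "approved", "atc_l", "cancerx", "ctrp"]
#: column order of the drug-table TSV export
_TABLE_COLUMNS = ["name", "approved", "atc_l", "cancerx", "score", "degree"]


@dataclass
class RankedResult:
    """Sorted score table plus the parameter / seed echo of the producing run."""

    rows: pd.DataFrame
    algorithm: str
    parameters: dict = field(default_factory=dict)
    seeds: frozenset[str] = frozenset()
    interactome_tag: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def node_ids(self) -> list[str]:
        return list(self.rows["node_id"])

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def write_tsv(self, path: str | Path) -> None:
        """Drug-table-shaped TSV: name, approved, atc_l, cancerx, score, degree."""
        out = self.rows.copy()
        out["score"] = out["normalized_score"]
        for c in ("approved", "atc_l", "cancerx"):
            out[c] = out[c].map(lambda b: "yes" if b is True else ("no" if b is False else ""))
        out[_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "algorithm": self.algorithm,
            "parameters": _jsonable(self.parameters),
            "seeds": sorted(self.seeds),
            "interactome_tag": self.interactome_tag,
            "rows": self.rows.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SummaryNetwork:
    """Union network over several task results with per-node occurrence counts."""

    graph: nx.Graph
    counts: dict[str, int]
    n_tasks: int
    interactome_tag: str = ""


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sort_and_normalize(df: pd.DataFrame) -> pd.DataFrame:
    mx = df["raw_score"].max() if len(df) else 0.0
    if mx > 0:
        df["normalized_score"] = df["raw_score"] / mx
    else:
        df["normalized_score"] = 0.0
        if len(df):
            logger.warning("all scores are zero; normalized scores set to 0")
    df = df.sort_values(
        by=["normalized_score", "degree", "node_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return df.reset_index(drop=True)


def rank_targets(
    result: ScoreMap | Subnetwork,
    interactome: Interactome,
    top_n: int | None = None,
    include_seeds: bool = False,
) -> RankedResult:
    """Ranked gene table from a target-capable result.

    Subnetwork inputs score member genes 1 and rank them by interactome
    degree.  The ``degree`` column is always the gene's degree in the full
    gene-gene interactome, not in the result subnetwork.  Seed rows are
    excluded unless ``include_seeds``.
    """
    if isinstance(result, ProximityResult):
        raise CapabilityError("network proximity is drug-repurposing only; it cannot rank targets")
    if isinstance(result, Subnetwork):
        entries = {n: 1.0 for n in result.nodes}
    else:
        entries = dict(result.scores)
    seeds = result.seeds
    recs = []
    for node, score in entries.items():
        gene = interactome.genes.get(node)
        if gene is None:  # drug rows never enter a target table
            continue
        recs.append({
            "node_id": node, "name": gene.symbol, "kind": "gene",
            "raw_score": float(score), "degree": interactome.gene_degree(node),
            "is_seed": node in seeds,
            "approved": None, "atc_l": None, "cancerx": None, "ctrp": None,
        })
    df = pd.DataFrame(recs, columns=_COLUMNS)
    if not include_seeds:
        df = df[~df["is_seed"]]
    df = _sort_and_normalize(df)
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return RankedResult(df, result.algorithm, dict(result.parameters), seeds,
                        result.interactome_tag)


def rank_drugs(
    result: ScoreMap | ProximityResult,
    interactome: Interactome,
    top_n: int | None = 15,
    include_unapproved: bool = True,
    include_indirect: bool = True,
    seeds: SeedSet | frozenset[str] | None = None,
) -> RankedResult:
    """Ranked drug table in the drug-search shape.

    Only propagation algorithms can rank drugs; aggregation results raise.
    "Indirect" drugs have no DGI edge to any seed and are excluded unless
    ``include_indirect``.  Score-based inputs are max-normalized (top row
    1); proximity ranks by ascending z with normalized score
    (max_z - z) / (max_z - min_z), so 1 stays "best".  The ``degree``
    column is the drug's degree in the full DGI interactome.
    """
    if isinstance(result, Subnetwork) or getattr(result, "algorithm", None) in AGGREGATION:
        raise CapabilityError(
            f"algorithm {getattr(result, 'algorithm', '?')!r} cannot rank drugs: "
            f"aggregation methods connect seeds and never reach the drug layer "
            f"(drug-capable: {sorted(DRUG_CAPABLE)})"
        )
    seed_ids = frozenset(seeds.genes if isinstance(seeds, SeedSet) else (seeds or result.seeds))

    def base_row(did: str) -> dict:
        d = interactome.drugs[did]
        return {
            "node_id": did, "name": d.name, "kind": "drug",
            "degree": interactome.drug_degree(did), "is_seed": False,
            "approved": d.approved, "atc_l": d.atc_l, "cancerx": d.cancerx, "ctrp": d.ctrp,
        }

    recs = []
    if isinstance(result, ProximityResult):
        zs = [r.z_score for r in result.records]
        if zs:
            z_min, z_max = min(zs), max(zs)
        for r in result.records:
            row = base_row(r.drug_id)
            row["raw_score"] = r.z_score
            row["normalized_score"] = (
                1.0 if z_max == z_min else (z_max - r.z_score) / (z_max - z_min)
            )
            recs.append(row)
        df = pd.DataFrame(recs, columns=_COLUMNS)
        df = df.sort_values(by=["raw_score", "degree", "node_id"],
                            ascending=[True, True, True], kind="mergesort").reset_index(drop=True)
    else:
        for did, score in result.scores.items():
            if did not in interactome.drugs:
                continue
            row = base_row(did)
            row["raw_score"] = float(score)
            recs.append(row)
        df = pd.DataFrame(recs, columns=_COLUMNS)
        df = _sort_and_normalize(df)

    if not include_unapproved:
        df = df[df["approved"]]
    if not include_indirect:
        direct = {e.drug for e in interactome.dgi if e.gene in seed_ids}
        df = df[df["node_id"].isin(direct)]
    df = df.reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return RankedResult(df, result.algorithm, dict(result.parameters), seed_ids,
                        result.interactome_tag)


def summarize_tasks(
    results: list,
    interactome: Interactome,
) -> SummaryNetwork:
    """Merge >= 2 task results into one network with occurrence counts.

    Nodes are the union over results; edges are the interactome edges
    induced on that union (GGI among included genes, DGI between included
    drugs and included genes); each node's count is the number of tasks
    containing it.
    """
    if len(results) < 2:
        raise ValueError("summarize_tasks needs at least 2 results")
    tags = {r.interactome_tag for r in results if r.interactome_tag}
    if len(tags) > 1:
        raise ValueError(f"results come from different interactomes: {sorted(tags)}")
    if tags and interactome.tag not in tags:
        raise ValueError("results were not computed on the given interactome")

    counts: dict[str, int] = {}
    for r in results:
        nodes = set(_result_nodes(r))
        for n in nodes:
            counts[n] = counts.get(n, 0) + 1

    G = nx.Graph(interactome_tag=interactome.tag)
    for n, c in counts.items():
        if n in interactome.genes:
            G.add_node(n, kind="gene", symbol=interactome.genes[n].symbol, count=c)
        elif n in interactome.drugs:
            G.add_node(n, kind="drug", symbol=interactome.drugs[n].name, count=c)
        else:
            G.add_node(n, kind="unknown", count=c)
    included = set(counts)
    for e in interactome.ggi:
        if e.gene_a in included and e.gene_b in included:
            G.add_edge(e.gene_a, e.gene_b)
    for e in interactome.dgi:
        if e.drug in included and e.gene in included:
            G.add_edge(e.drug, e.gene)
    return SummaryNetwork(G, counts, len(results), interactome.tag)


def _result_nodes(r) -> list[str]:
    if isinstance(r, RankedResult):
        return r.node_ids()
    if isinstance(r, Subnetwork):
        return sorted(r.nodes)
    if isinstance(r, ScoreMap):
        return sorted(r.scores)
    if isinstance(r, ProximityResult):
        return sorted(rec.drug_id for rec in r.records)
    raise TypeError(f"cannot extract nodes from {type(r).__name__}")


def mst_view(graph: nx.Graph, node_subset: set[str]) -> Subnetwork:
    """Declutter view: connect a node subset through a minimum spanning tree.

    The MST is computed over the metric closure (pairwise shortest-path
    costs) of the subset and closure edges are expanded back to their
    underlying paths, so nodes outside the subset appear only as path
    connectors.  Disconnected subsets yield one tree per component.
    """
    subset = set(node_subset)
    if not subset:
        raise ValueError("node_subset must be nonempty")
    missing = subset - set(graph.nodes)
    if missing:
        raise ValueError(f"subset node(s) not in graph: {sorted(missing)}")

    closure = nx.Graph()
    closure.add_nodes_from(subset)
    paths: dict[tuple[str, str], list[str]] = {}
    for s in sorted(subset):
        dist, path = nx.single_source_dijkstra(graph, s, weight=_cost_of)
        for t in subset:
            if t <= s or t not in dist:
                continue
            closure.add_edge(s, t, cost=dist[t])
            paths[(s, t)] = path[t]

    nodes: set[str] = set(subset)
    edges: set[tuple[str, str]] = set()
    for u, v in nx.minimum_spanning_edges(closure, weight="cost", data=False):
        p = paths[(u, v) if (u, v) in paths else (v, u)]
        nodes.update(p)
        edges.update(_ekey(a, b) for a, b in zip(p, p[1:]))
    return Subnetwork(nodes, edges, "mst_view", {}, frozenset(),
                      graph.graph.get("interactome_tag", ""))
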