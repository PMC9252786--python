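"""Annotated gene-drug interactome: data model, TSV I/O and working graphs.

The interactome has two node layers. Genes form an undirected gene-gene
interaction (GGI) network annotated with cancer-driver catalog membership,
per-cancer-type somatic mutation frequencies and per-tissue expression.
Drugs attach to genes through a bipartite drug-gene interaction (DGI) layer
labelled with the action of the drug on its target (inhibitor / activator /
other) and carry approval and anticancer-catalog flags.

Two working graphs are derived for the algorithms:

* :func:`gene_graph` -- an undirected :class:`networkx.Graph` over genes
  whose edges carry a strictly positive traversal ``cost`` (for shortest
  paths) and a ``weight`` multiplier (for random walks), both derived from
  a :class:`WeightingScheme`.
* :func:`drug_gene_graph` -- a :class:`networkx.DiGraph` layering filtered
  drugs on top of the gene graph.  Gene-gene edges appear in both
  directions while drug edges point gene->drug only, so drugs are strict
  sinks: no path between two genes can ever pass through a drug, and every
  gene-gene shortest path equals its gene-graph counterpart by
  construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger("drugnet")

ACTIONS = ("inhibitor", "activator", "other")
WEIGHT_SOURCES = ("none", "mutation_frequency", "expression")


class DrugnetError(Exception):
    """Base class for all package errors."""


class ParseError(DrugnetError):
    """A malformed input file row (carries file and line number)."""


class UnknownContextError(DrugnetError):
    """A weighting context key absent from every gene annotation."""


@dataclass
class Gene:
    gene_id: str
    symbol: str = ""
    # cancer type -> set of driver catalog names
    driver_sources: dict[str, set[str]] = field(default_factory=dict)
    # cancer type -> somatic mutation frequency in [0, 1]
    mutation_frequency: dict[str, float] = field(default_factory=dict)
    # tissue -> non-negative TPM-like expression value
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbol:
            self.symbol = self.gene_id
        for ctx, f in self.mutation_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"mutation frequency for {self.gene_id}/{ctx} outside [0,1]: {f}"
                )
        for ctx, v in self.expression.items():
            if v < 0:
                raise ValueError(
                    f"negative expression for {self.gene_id}/{ctx}: {v}"
                )


@dataclass
class Drug:
    drug_id: str
    name: str = ""
    approved: bool = False   # FDA, EMA or HC approval, collapsed at load time
    atc_l: bool = False      # WHO ATC class L: antineoplastic or immunomodulating
    cancerx: bool = False    # curated approved-anticancer-drug list
    ctrp: bool = False       # evaluated in CTRP cell-line studies

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.drug_id


@dataclass(frozen=True)
class GeneInteraction:
    gene_a: str
    gene_b: str
    dataset: str = "default"


@dataclass(frozen=True)
class DrugGeneInteraction:
    drug: str
    gene: str
    action: str = "other"
    dataset: str = "default"

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown DGI action {self.action!r}; expected one of {ACTIONS}")


@dataclass(frozen=True)
class WeightingScheme:
    """How gene annotations turn into edge costs / walk multipliers.

    ``source`` selects the annotation (``none`` disables weighting);
    ``context`` is the cancer type (mutation) or tissue (expression) the
    annotation is read for.  With per-gene annotation ``a`` rescaled to
    [0, 1] across the interactome, an edge (u, v) gets

    * traversal cost ``c = 1 / (1 + mean(a_u, a_v))`` in [1/2, 1], so
      shortest paths prefer highly mutated / highly expressed genes, and
    * random-walk multiplier ``w = 1 + mean(a_u, a_v)`` in [1, 2], so
      walks prefer the same regions after row normalization.

    Unannotated genes (and drugs) contribute ``a = 0``.
    """

    source: str = "none"
    context: str | None = None
    transform: str = "inverse_mean"

    def __post_init__(self) -> None:
        if self.source not in WEIGHT_SOURCES:
            raise ValueError(f"unknown weighting source {self.source!r}")
        if self.source != "none" and not self.context:
            raise ValueError("weighting context required when source != 'none'")


@dataclass(frozen=True)
class DrugFilters:
    """Conjunctive drug inclusion flags for the drug layer."""

    approved_only: bool = False
    ctrp_only: bool = False
    atc_l_only: bool = False
    cancerx_only: bool = False

    def admits(self, drug: Drug) -> bool:
        if self.approved_only and not drug.approved:
            return False
        if self.ctrp_only and not drug.ctrp:
            return False
        if self.atc_l_only and not drug.atc_l:
            return False
        if self.cancerx_only and not drug.cancerx:
            return False
        return True


class Interactome:
    """Container for genes, drugs and their (deduplicated) interactions."""

    def __init__(
        self,
        genes: Iterable[Gene] = (),
        drugs: Iterable[Drug] = (),
        ggi: Iterable[GeneInteraction] = (),
        dgi: Iterable[DrugGeneInteraction] = (),
    ) -> None:
        self.genes: dict[str, Gene] = {}
        self.drugs: dict[str, Drug] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        for d in drugs:
            if d.drug_id in self.drugs:
                raise ValueError(f"duplicate drug_id {d.drug_id!r}")
            self.drugs[d.drug_id] = d

        self.ggi: list[GeneInteraction] = []
        self.dgi: list[DrugGeneInteraction] = []
        self._ggi_seen: set[tuple[str, str, str]] = set()
        self._dgi_seen: set[tuple[str, str, str]] = set()
        dropped_self = dropped_dup = 0
        for e in ggi:
            status = self._add_ggi(e)
            dropped_self += status == "self"
            dropped_dup += status == "dup"
        for e in dgi:
            if not self._add_dgi(e):
                dropped_dup += 1
        if dropped_self or dropped_dup:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s) while building interactome",
                dropped_self, dropped_dup,
            )

    # -- construction helpers -------------------------------------------------

    def _add_ggi(self, e: GeneInteraction) -> str:
        if e.gene_a == e.gene_b:
            return "self"
        a, b = sorted((e.gene_a, e.gene_b))
        key = (a, b, e.dataset)
        if key in self._ggi_seen:
            return "dup"
        self._ggi_seen.add(key)
        for gid in (a, b):
            self.genes.setdefault(gid, Gene(gid))
        self.ggi.append(GeneInteraction(a, b, e.dataset))
        return "ok"

    def _add_dgi(self, e: DrugGeneInteraction) -> bool:
        key = (e.drug, e.gene, e.dataset)
        if key in self._dgi_seen:
            return False
        self._dgi_seen.add(key)
        self.drugs.setdefault(e.drug, Drug(e.drug))
        self.genes.setdefault(e.gene, Gene(e.gene))
        self.dgi.append(e)
        return True

    # -- queries --------------------------------------------------------------

    def gene_neighbors(self, gene_id: str) -> set[str]:
        nbrs = set()
        for e in self.ggi:
            if e.gene_a == gene_id:
                nbrs.add(e.gene_b)
            elif e.gene_b == gene_id:
                nbrs.add(e.gene_a)
        return nbrs

    def gene_degree(self, gene_id: str) -> int:
        """Degree in the simple (dataset-collapsed) gene-gene network."""
        return len({tuple(sorted((e.gene_a, e.gene_b)))
                    for e in self.ggi if gene_id in (e.gene_a, e.gene_b)})

    def drug_degree(self, drug_id: str) -> int:
        """Number of distinct target genes in the DGI layer."""
        return len({e.gene for e in self.dgi if e.drug == drug_id})

    def drug_targets(self, drug_id: str, actions: Iterable[str] = ACTIONS) -> set[str]:
        allowed = set(actions)
        return {e.gene for e in self.dgi if e.drug == drug_id and e.action in allowed}

    def driver_catalogs(self) -> set[str]:
        cats: set[str] = set()
        for g in self.genes.values():
            for srcs in g.driver_sources.values():
                cats |= srcs
        return cats

    @property
    def tag(self) -> str:
        """Stable content hash identifying the interactome instance."""
        h = hashlib.sha256()
        for gid in sorted(self.genes):
            h.update(gid.encode())
        for did in sorted(self.drugs):
            h.update(did.encode())
        for key in sorted(self._ggi_seen):
            h.update("|".join(key).encode())
        for key in sorted(self._dgi_seen):
            h.update("|".join(key).encode())
        return h.hexdigest()[:12]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Interactome({len(self.genes)} genes, {len(self.drugs)} drugs, "
                f"{len(self.ggi)} GGI, {len(self.dgi)} DGI)")


# -- annotation rescaling -----------------------------------------------------

def _rescaled_annotation(interactome: Interactome, weighting: WeightingScheme) -> dict[str, float]:
    """Per-gene annotation for the scheme's context, rescaled to [0, 1].

    Missing values are 0.  Raises :class:`UnknownContextError` when the
    context key appears in no gene's annotations.
    """
    if weighting.source == "none":
        return {}
    attr = "mutation_frequency" if weighting.source == "mutation_frequency" else "expression"
    ctx = weighting.context
    raw = {gid: getattr(g, attr).get(ctx, 0.0) for gid, g in interactome.genes.items()}
    if not any(ctx in getattr(g, attr) for g in interactome.genes.values()):
        known = sorted({k for g in interactome.genes.values() for k in getattr(g, attr)})
        raise UnknownContextError(
            f"context {ctx!r} not found in any gene {attr} annotation; known contexts: {known}"
        )
    mx = max(raw.values())
    if mx <= 0:
        return {gid: 0.0 for gid in raw}
    return {gid: v / mx for gid, v in raw.items()}


def edge_cost(a_u: float, a_v: float) -> float:
    """Traversal cost for an edge between annotations a_u, a_v in [0,1]."""
    return 1.0 / (1.0 + 0.5 * (a_u + a_v))


def edge_multiplier(a_u: float, a_v: float) -> float:
    """Random-walk preference multiplier for the same edge."""
    return 1.0 + 0.5 * (a_u + a_v)


# -- working graphs -----------------------------------------------------------

def gene_graph(interactome: Interactome, weighting: WeightingScheme | None = None) -> nx.Graph:
    """Undirected weighted graph over all genes and GGI edges.

    Every edge carries ``cost`` (shortest-path traversal cost, strictly
    positive) and ``weight`` (random-walk multiplier).  With
    ``weighting.source == 'none'`` all costs and weights equal 1.
    """
    weighting = weighting or WeightingScheme()
    a = _rescaled_annotation(interactome, weighting)
    G = nx.Graph(interactome_tag=interactome.tag)
    for gid, g in interactome.genes.items():
        G.add_node(gid, kind="gene", symbol=g.symbol)
    seen = set()
    for e in interactome.ggi:
        key = (e.gene_a, e.gene_b)
        if key in seen:
            continue
        seen.add(key)
        au, av = a.get(e.gene_a, 0.0), a.get(e.gene_b, 0.0)
        G.add_edge(e.gene_a, e.gene_b, cost=edge_cost(au, av), weight=edge_multiplier(au, av))
    return G


def drug_gene_graph(
    interactome: Interactome,
    weighting: WeightingScheme | None = None,
    action_filter: Iterable[str] = ACTIONS,
    drug_filters: DrugFilters | None = None,
) -> nx.DiGraph:
    """Layered graph: gene core plus filtered drug sinks.

    Gene-gene edges are inserted in both directions, drug edges only
    gene->drug, which makes the sink contract structural: a drug has no
    outgoing edge, hence never mediates gene-gene connectivity.  Only
    drugs passing all enabled :class:`DrugFilters` flags with at least one
    DGI edge whose action is in ``action_filter`` are retained.
    """
    actions = set(action_filter)
    if not actions:
        raise ValueError("action_filter must allow at least one action")
    unknown = actions - set(ACTIONS)
    if unknown:
        raise ValueError(f"unknown DGI action(s) {sorted(unknown)}; expected subset of {ACTIONS}")
    drug_filters = drug_filters or DrugFilters()
    weighting = weighting or WeightingScheme()
    a = _rescaled_annotation(interactome, weighting)

    D = nx.DiGraph(interactome_tag=interactome.tag)
    base = gene_graph(interactome, weighting)
    for n, data in base.nodes(data=True):
        D.add_node(n, **data)
    for u, v, data in base.edges(data=True):
        D.add_edge(u, v, **data)
        D.add_edge(v, u, **data)

    kept = 0
    for e in interactome.dgi:
        if e.action not in actions:
            continue
        drug = interactome.drugs[e.drug]
        if not drug_filters.admits(drug):
            continue
        if e.drug not in D:
            D.add_node(e.drug, kind="drug", symbol=drug.name,
                       approved=drug.approved, atc_l=drug.atc_l,
                       cancerx=drug.cancerx, ctrp=drug.ctrp)
            kept += 1
        if not D.has_edge(e.gene, e.drug):
            ag = a.get(e.gene, 0.0)
            D.add_edge(e.gene, e.drug, cost=edge_cost(ag, 0.0), weight=edge_multiplier(ag, 0.0))
    if kept == 0 and interactome.drugs:
        logger.warning("all %d drugs filtered out of the drug-gene graph", len(interactome.drugs))
    return D


def drug_nodes(G: nx.Graph | nx.DiGraph) -> set[str]:
    return {n for n, k in G.nodes(data="kind") if k == "drug"}


def gene_subgraph(G: nx.Graph | nx.DiGraph) -> nx.Graph:
    """Undirected gene-only view of a working graph."""
    genes = [n for n, k in G.nodes(data="kind") if k != "drug"]
    H = G.subgraph(genes)
    return nx.Graph(H) if H.is_directed() else H


# -- TSV I/O ------------------------------------------------------------------

_GGI_HEADER = ["gene_a", "gene_b", "dataset"]
_DGI_HEADER = ["drug_id", "gene_id", "action", "dataset"]
_GENE_ATTR_HEADER = ["gene_id", "context_kind", "context", "value"]
_DRUG_ATTR_HEADER = ["drug_id", "name", "approved", "atc_l", "cancerx", "ctrp"]


def _read_tsv(path: str | Path, expected_header: list[str]):
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, expected header {expected_header}")
    header = lines[0].split("\t")
    if header != expected_header:
        raise ParseError(f"{path}:1: expected header {expected_header}, got {header}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(expected_header):
            raise ParseError(
                f"{path}:{i}: expected {len(expected_header)} tab-separated fields, got {len(parts)}"
            )
        rows.append((i, parts))
    return path, rows


def load_interactome(
    ggi_path: str | Path,
    dgi_path: str | Path | None = None,
    gene_attr_path: str | Path | None = None,
    drug_attr_path: str | Path | None = None,
) -> Interactome:
    """Load an interactome from the package's TSV dialects.

    Nodes appearing only in edge files are created with empty annotations;
    duplicate edges and self-loops are dropped (counts are logged);
    attribute rows for unknown nodes are skipped with a warning.
    """
    _, ggi_rows = _read_tsv(ggi_path, _GGI_HEADER)
    ggi = [GeneInteraction(a, b, ds) for _, (a, b, ds) in ggi_rows]

    dgi: list[DrugGeneInteraction] = []
    if dgi_path is not None:
        p, dgi_rows = _read_tsv(dgi_path, _DGI_HEADER)
        for line_no, (drug, gene, action, ds) in dgi_rows:
            if action not in ACTIONS:
                raise ParseError(f"{p}:{line_no}: unknown DGI action {action!r}")
            dgi.append(DrugGeneInteraction(drug, gene, action, ds))

    inter = Interactome(ggi=ggi, dgi=dgi)

    if gene_attr_path is not None:
        p, rows = _read_tsv(gene_attr_path, _GENE_ATTR_HEADER)
        for line_no, (gid, kind, ctx, value) in rows:
            gene = inter.genes.get(gid)
            if gene is None:
                logger.warning("%s:%d: unknown gene %r, attribute row skipped", p, line_no, gid)
                continue
            if kind == "symbol":
                gene.symbol = value
            elif kind == "driver":
                gene.driver_sources.setdefault(ctx, set()).add(value)
            elif kind == "mutation":
                f = _parse_float(p, line_no, value)
                if not 0.0 <= f <= 1.0:
                    raise ParseError(f"{p}:{line_no}: mutation frequency outside [0,1]: {f}")
                gene.mutation_frequency[ctx] = f
            elif kind == "expression":
                v = _parse_float(p, line_no, value)
                if v < 0:
                    raise ParseError(f"{p}:{line_no}: negative expression value: {v}")
                gene.expression[ctx] = v
            else:
                raise ParseError(f"{p}:{line_no}: unknown context_kind {kind!r}")

    if drug_attr_path is not None:
        p, rows = _read_tsv(drug_attr_path, _DRUG_ATTR_HEADER)
        for line_no, (did, name, approved, atc_l, cancerx, ctrp) in rows:
            drug = inter.drugs.get(did)
            if drug is None:
                logger.warning("%s:%d: unknown drug %r, attribute row skipped", p, line_no, did)
                continue
            drug.name = name
            drug.approved = _parse_bool(p, line_no, approved)
            drug.atc_l = _parse_bool(p, line_no, atc_l)
            drug.cancerx = _parse_bool(p, line_no, cancerx)
            drug.ctrp = _parse_bool(p, line_no, ctrp)
    return inter


def _parse_float(path, line_no, token) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{line_no}: expected a number, got {token!r}") from exc


def _parse_bool(path, line_no, token) -> bool:
    if token in ("0", "1"):
        return token == "1"
    raise ParseError(f"{path}:{line_no}: expected 0/1 boolean, got {token!r}")


def write_interactome(
    interactome: Interactome,
    ggi_path: str | Path,
    dgi_path: str | Path,
    gene_attr_path: str | Path,
    drug_attr_path: str | Path,
) -> None:
    """Serialize to the TSV dialects read by :func:`load_interactome`."""
    with open(ggi_path, "w") as fh:
        fh.write("\t".join(_GGI_HEADER) + "\n")
        for e in sorted(interactome.ggi, key=lambda e: (e.gene_a, e.gene_b, e.dataset)):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.dataset}\n")
    with open(dgi_path, "w") as fh:
        fh.write("\t".join(_DGI_HEADER) + "\n")
        for e in sorted(interactome.dgi, key=lambda e: (e.drug, e.gene, e.dataset)):
            fh.write(f"{e.drug}\t{e.gene}\t{e.action}\t{e.dataset}\n")
    with open(gene_attr_path, "w") as fh:
        fh.write("\t".join(_GENE_ATTR_HEADER) + "\n")
        for gid in sorted(interactome.genes):
            g = interactome.genes[gid]
            fh.write(f"{gid}\tsymbol\t\t{g.symbol}\n")
            for ctx in sorted(g.driver_sources):
                for cat in sorted(g.driver_sources[ctx]):
                    fh.write(f"{gid}\tdriver\t{ctx}\t{cat}\n")
            for ctx in sorted(g.mutation_frequency):
                fh.write(f"{gid}\tmutation\t{ctx}\t{g.mutation_frequency[ctx]!r}\n")
            for ctx in sorted(g.expression):
                fh.write(f"{gid}\texpression\t{ctx}\t{g.expression[ctx]!r}\n")
    with open(drug_attr_path, "w") as fh:
        fh.write("\t".join(_DRUG_ATTR_HEADER) + "\n")
        for did in sorted(interactome.drugs):
            d = interactome.drugs[did]
            flags = "\t".join(str(int(b)) for b in (d.approved, d.atc_l, d.cancerx, d.ctrp))
            fh.write(f"{did}\t{d.name}\t{flags}\n")


# -- network export -----------------------------------------------------------

def to_node_link(G: nx.Graph | nx.DiGraph) -> dict:
    """Node-link JSON dict (nodes carry kind and flags, links carry cost)."""
    return nx.node_link_data(G, edges="links")


def write_node_link_json(G: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(to_node_link(G), fh, indent=1, sort_keys=True)


def write_graphml(G: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(G, path)
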