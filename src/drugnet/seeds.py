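"""Seed-gene selection.

Seed genes anchor every network algorithm.  Four constructors build a
:class:`SeedSet` from (i) cancer-driver catalog flags, (ii) mutation
frequency / expression thresholds, (iii) a user-supplied token list and
(iv) a PolyPhen-2-style variant score table.  Seed sets compose by set
algebra with provenance merged by union; an empty set is a legal value
and only rejected when an algorithm is invoked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .interactome import DrugnetError, Interactome, ParseError

logger = logging.getLogger("drugnet")


class EmptySeedError(DrugnetError):
    """Raised when an algorithm is invoked with no resolved seeds."""


@dataclass
class SeedSet:
    """Resolved seed genes with per-gene provenance of the selection rules.

    ``unresolved`` lists input tokens that matched no interactome gene;
    they are reported, never silently dropped.
    """

    genes: frozenset[str] = frozenset()
    provenance: dict[str, set[str]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        for g in self.genes:
            self.provenance.setdefault(g, set())
        extra = set(self.provenance) - self.genes
        if extra:
            raise ValueError(f"provenance keys not in seed genes: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __or__(self, other: "SeedSet") -> "SeedSet":
        prov = {g: set(tags) for g, tags in self.provenance.items()}
        for g, tags in other.provenance.items():
            prov.setdefault(g, set()).update(tags)
        return SeedSet(self.genes | other.genes, prov,
                       _dedup(self.unresolved + other.unresolved))

    def __and__(self, other: "SeedSet") -> "SeedSet":
        genes = self.genes & other.genes
        prov = {g: self.provenance.get(g, set()) | other.provenance.get(g, set())
                for g in genes}
        return SeedSet(genes, prov, _dedup(self.unresolved + other.unresolved))

    def require_nonempty(self) -> "SeedSet":
        if not self.genes:
            raise EmptySeedError("seed set is empty; algorithms need at least one seed gene")
        return self


def _dedup(tokens: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for t in tokens:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def seeds_from_drivers(
    interactome: Interactome,
    cancer_type: str = "",
    sources: set[str] | None = None,
) -> SeedSet:
    """Genes flagged by the given driver catalogs for a cancer type.

    An empty ``cancer_type`` means "any context".  ``sources`` defaults to
    every catalog present in the interactome; unknown catalog names raise.
    """
    valid = interactome.driver_catalogs()
    sources = set(sources) if sources is not None else set(valid)
    unknown = sources - valid
    if unknown:
        raise DrugnetError(
            f"unknown driver catalog(s) {sorted(unknown)}; valid catalogs: {sorted(valid)}"
        )
    prov: dict[str, set[str]] = {}
    for gid, gene in interactome.genes.items():
        contexts = gene.driver_sources if not cancer_type else {
            cancer_type: gene.driver_sources.get(cancer_type, set())
        }
        matched = set()
        for cats in contexts.values():
            matched |= cats & sources
        if matched:
            prov[gid] = {f"driver:{cat}" for cat in matched}
    if not prov:
        logger.warning("no genes carry driver flags for cancer_type=%r sources=%s",
                       cancer_type, sorted(sources))
    return SeedSet(frozenset(prov), prov)


def seeds_from_thresholds(
    interactome: Interactome,
    cancer_type: str | None = None,
    min_mutation_frequency: float | None = None,
    tissue: str | None = None,
    min_expression: float | None = None,
) -> SeedSet:
    """Genes passing the conjunction of the enabled annotation thresholds.

    A gene missing an annotation fails that threshold.  At least one of
    ``min_mutation_frequency`` / ``min_expression`` must be given.
    """
    if min_mutation_frequency is None and min_expression is None:
        raise DrugnetError("no criterion: give min_mutation_frequency and/or min_expression")
    if min_mutation_frequency is not None and cancer_type is None:
        raise DrugnetError("cancer_type required with min_mutation_frequency")
    if min_expression is not None and tissue is None:
        raise DrugnetError("tissue required with min_expression")
    prov: dict[str, set[str]] = {}
    for gid, gene in interactome.genes.items():
        tags = set()
        if min_mutation_frequency is not None:
            f = gene.mutation_frequency.get(cancer_type)
            if f is None or f < min_mutation_frequency:
                continue
            tags.add(f"mutation>={min_mutation_frequency}:{cancer_type}")
        if min_expression is not None:
            v = gene.expression.get(tissue)
            if v is None or v < min_expression:
                continue
            tags.add(f"expression>={min_expression}:{tissue}")
        prov[gid] = tags
    return SeedSet(frozenset(prov), prov)


def seeds_from_list(interactome: Interactome, tokens: list[str]) -> SeedSet:
    """Resolve user tokens: exact gene_id first, then case-insensitive symbol."""
    if not tokens:
        raise DrugnetError("token list is empty")
    by_symbol: dict[str, set[str]] = {}
    for gid, gene in interactome.genes.items():
        by_symbol.setdefault(gene.symbol.casefold(), set()).add(gid)
    by_id_ci = {gid.casefold(): gid for gid in interactome.genes}

    prov: dict[str, set[str]] = {}
    unresolved: list[str] = []
    for tok in tokens:
        t = tok.strip()
        if not t:
            continue
        if t in interactome.genes:
            prov.setdefault(t, set()).add("list:id")
        elif t.casefold() in by_id_ci:
            prov.setdefault(by_id_ci[t.casefold()], set()).add("list:id")
        elif t.casefold() in by_symbol:
            for gid in by_symbol[t.casefold()]:
                prov.setdefault(gid, set()).add("list:symbol")
        else:
            unresolved.append(tok)
    return SeedSet(frozenset(prov), prov, _dedup(unresolved))


def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene list; ``#`` comments and blank lines ignored."""
    tokens = []
    for line in Path(path).read_text().splitlines():
        t = line.split("#", 1)[0].strip()
        if t:
            tokens.append(t)
    return tokens


def seeds_from_polyphen(
    interactome: Interactome,
    table_path: str | Path,
    min_score: float = 0.85,
    category: str | None = None,
    gene_column: str = "gene",
    score_column: str = "pph2_prob",
    prediction_column: str = "prediction",
) -> SeedSet:
    """Genes with at least one damaging variant in a PolyPhen-2-style table.

    A variant qualifies when its damaging probability is >= ``min_score``
    (and its categorical prediction equals ``category`` when given).
    Provenance records the qualifying variant count per gene.
    """
    path = Path(table_path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty variant table")
    header = [h.strip() for h in lines[0].split("\t")]
    try:
        gi = header.index(gene_column)
        si = header.index(score_column)
        pi = header.index(prediction_column)
    except ValueError as exc:
        raise ParseError(f"{path}:1: missing required column in header {header}: {exc}") from exc

    counts: dict[str, int] = {}
    unresolved: list[str] = []
    by_symbol = {g.symbol.casefold(): gid for gid, g in interactome.genes.items()}
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}:{line_no}: expected {len(header)} fields, got {len(parts)}")
        token, score_s, pred = parts[gi].strip(), parts[si].strip(), parts[pi].strip()
        try:
            score = float(score_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: non-numeric score {score_s!r}") from exc
        if not 0.0 <= score <= 1.0:
            raise ParseError(f"{path}:{line_no}: score outside [0,1]: {score}")
        if score < min_score:
            continue
        if category is not None and pred != category:
            continue
        gid = token if token in interactome.genes else by_symbol.get(token.casefold())
        if gid is None:
            unresolved.append(token)
            continue
        counts[gid] = counts.get(gid, 0) + 1
    prov = {g: {f"polyphen:{n}_variants>= {min_score}".replace(" ", "")} for g, n in counts.items()}
    return SeedSet(frozenset(prov), prov, _dedup(unresolved))
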