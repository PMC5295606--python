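"""Core domain types: genes, the weighted functional network, genetic
interaction records, seed sets, and protein complexes.

A *functional gene network* is an undirected graph over genes whose edge
weights are log likelihood scores (LLS) quantifying confidence that the two
genes act in the same biological process.  A *seed set* is a query gene
together with its known genetic interaction partners of one interaction
class; it is the unit evaluated by the prediction method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

logger = logging.getLogger(__name__)

#: Gene identifiers are opaque strings (Entrez IDs or systematic names),
#: compared by exact string equality after whitespace trimming.
Gene = str


def normalize_gene(raw: str) -> Gene:
    """Trim whitespace and reject empty identifiers."""
    g = str(raw).strip()
    if not g:
        raise ValueError("gene identifier must be non-empty")
    return g


@dataclass(frozen=True)
class InteractionRecord:
    """One known genetic interaction between two distinct genes.

    Records are unordered: ``(a, b)`` and ``(b, a)`` of the same type denote
    the same interaction, so the pair is stored in sorted order.
    """

    a: Gene
    b: Gene
    interaction_type: str = ""
    organism: Optional[str] = None
    year: Optional[int] = None

    def __post_init__(self) -> None:
        a = normalize_gene(self.a)
        b = normalize_gene(self.b)
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a!r}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def pair(self) -> tuple[Gene, Gene]:
        return (self.a, self.b)


def interacting_pairs(records: Iterable[InteractionRecord]) -> set[tuple[Gene, Gene]]:
    """Distinct unordered gene pairs in a record collection (types pooled)."""
    return {r.pair for r in records}


def degree(
    records: Iterable[InteractionRecord],
    gene: Gene,
    interaction_type: Optional[str] = None,
) -> int:
    """Genetic interaction degree: the number of distinct partners of ``gene``.

    With ``interaction_type`` set, only records of that class (matched
    case-insensitively after trimming) are counted.  A gene absent from all
    records has degree 0.
    """
    g = normalize_gene(gene)
    if interaction_type is not None:
        want = interaction_type.strip().lower()
        records = (r for r in records if r.interaction_type.strip().lower() == want)
    partners = set()
    for r in records:
        if r.a == g:
            partners.add(r.b)
        elif r.b == g:
            partners.add(r.a)
    return len(partners)


class FunctionalNetwork:
    """Undirected weighted gene network with LLS edge weights.

    Invariants: no self-edges, at most one edge per unordered pair,
    symmetric finite non-negative weights.  Duplicate edges presented with
    conflicting weights keep the maximum and log a warning.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[Gene, Gene, float]]) -> "FunctionalNetwork":
        net = cls()
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    def add_gene(self, g: Gene) -> None:
        self._g.add_node(normalize_gene(g))

    def add_edge(self, a: Gene, b: Gene, weight: float) -> None:
        a = normalize_gene(a)
        b = normalize_gene(b)
        w = float(weight)
        if a == b:
            raise ValueError(f"self-edge not allowed: {a!r}")
        if not math.isfinite(w) or w < 0:
            raise ValueError(f"edge weight must be finite and >= 0, got {weight!r}")
        if self._g.has_edge(a, b):
            old = self._g[a][b]["weight"]
            if old != w:
                logger.warning(
                    "duplicate edge %s-%s with conflicting weights %g/%g; keeping max",
                    a, b, old, w,
                )
            w = max(old, w)
        self._g.add_edge(a, b, weight=w)

    # -- queries -----------------------------------------------------------

    @property
    def genes(self) -> set[Gene]:
        return set(self._g.nodes)

    @property
    def n_genes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, g: Gene) -> bool:
        return g in self._g

    def has_edge(self, a: Gene, b: Gene) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: Gene, b: Gene) -> float:
        """Edge weight, 0.0 when the pair is not linked."""
        data = self._g.get_edge_data(a, b)
        return 0.0 if data is None else data["weight"]

    def neighbors(self, g: Gene) -> Iterator[tuple[Gene, float]]:
        if g not in self._g:
            return iter(())
        return ((nbr, d["weight"]) for nbr, d in self._g[g].items())

    def edges(self) -> Iterator[tuple[Gene, Gene, float]]:
        for a, b, d in self._g.edges(data=True):
            yield a, b, d["weight"]

    def sorted_edges(self) -> list[tuple[Gene, Gene, float]]:
        """Edges with each pair sorted and the list ordered lexicographically
        (canonical form for serialization and equality)."""
        out = []
        for a, b, w in self.edges():
            if b < a:
                a, b = b, a
            out.append((a, b, w))
        out.sort()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FunctionalNetwork):
            return NotImplemented
        return self.genes == other.genes and self.sorted_edges() == other.sorted_edges()

    def __repr__(self) -> str:
        return f"FunctionalNetwork({self.n_genes} genes, {self.n_edges} edges)"


@dataclass(frozen=True)
class SeedSet:
    """A query gene plus its known genetic interaction partners of one class."""

    seed: Gene
    partners: frozenset = field(default_factory=frozenset)
    interaction_type: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed", normalize_gene(self.seed))
        object.__setattr__(self, "partners", frozenset(normalize_gene(p) for p in self.partners))
        if self.seed in self.partners:
            raise ValueError(f"seed {self.seed!r} cannot be its own partner")
        if len(self.partners) < 2:
            raise ValueError("a seed set needs at least 2 partners")


@dataclass(frozen=True)
class ProteinComplex:
    """A named set of genes forming a protein complex.

    Complexes with fewer than 2 members are representable but are flagged
    ineligible for enrichment analysis.
    """

    id: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "id", str(self.id).strip())
        object.__setattr__(self, "members", frozenset(normalize_gene(m) for m in self.members))
        if not self.id:
            raise ValueError("complex id must be non-empty")

    @property
    def eligible(self) -> bool:
        return len(self.members) >= 2
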