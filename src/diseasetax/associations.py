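"""Disease-gene association tables and Jaccard similarity matrices.

A disease is represented by the set of genes associated with it, a gene by
the set of diseases it is associated with.  Pairwise similarity in either
direction is the Jaccard index of the two sets:

    disease_sim(A, B) = |G_A ∩ G_B| / |G_A ∪ G_B|
    gene_sim(g1, g2)  = |D_g1 ∩ D_g2| / |D_g1 ∪ D_g2|

Distances used by the inference methods are ``1 - similarity``.

Identifiers are opaque, case-sensitive strings; no symbol normalisation is
attempted.  Diseases without any associated gene cannot be scored — they
are rejected here and must be pruned from the reference hierarchy first
(see :mod:`diseasetax.reference`).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "SimilarityMatrix",
    "DistanceMatrix",
    "read_associations",
    "merge_tables",
    "disease_similarity",
    "gene_similarity",
    "build_similarity_matrix",
    "to_distance",
]


@dataclass
class AssociationTable:
    """A deduplicated set of (disease_id, gene_id) pairs.

    Maintains both directions of the bipartite incidence so that disease
    and gene similarities are O(set size) lookups.
    """

    records: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._by_disease: dict[str, set[str]] = {}
        self._by_gene: dict[str, set[str]] = {}
        for d, g in self.records:
            if not d or not g:
                raise DomainError("association ids must be non-empty strings")
            self._by_disease.setdefault(d, set()).add(g)
            self._by_gene.setdefault(g, set()).add(d)

    @property
    def diseases(self) -> set[str]:
        return set(self._by_disease)

    @property
    def genes(self) -> set[str]:
        return set(self._by_gene)

    def genes_of(self, disease_id: str) -> set[str]:
        """Gene set G of a disease; empty set for an unknown disease."""
        return set(self._by_disease.get(disease_id, ()))

    def diseases_of(self, gene_id: str) -> set[str]:
        """Disease set D of a gene; empty set for an unknown gene."""
        return set(self._by_gene.get(gene_id, ()))

    def __len__(self) -> int:
        return len(self.records)


def read_associations(path) -> AssociationTable:
    """Read a two-column TSV of ``disease_id<TAB>gene_id`` pairs.

    Lines starting with ``#`` and blank lines are ignored.  Duplicate
    pairs are dropped.  A row without exactly two tab-separated fields
    raises :class:`ParseError` naming the line number.
    """
    records: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            d, g = fields[0].strip(), fields[1].strip()
            if not d or not g:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            records.add((d, g))
    table = AssociationTable(records)
    logger.info(
        "read %s: %d diseases, %d genes, %d pairs",
        path, len(table.diseases), len(table.genes), len(table),
    )
    return table


def merge_tables(tables: Sequence[AssociationTable]) -> AssociationTable:
    """Set union of several association tables (e.g. OMIM + Genopedia)."""
    if not tables:
        raise DomainError("merge_tables requires at least one table")
    merged: set[tuple[str, str]] = set()
    for t in tables:
        merged |= t.records
    return AssociationTable(merged)


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def disease_similarity(table: AssociationTable, a: str, b: str) -> float:
    """Jaccard index of the gene sets of diseases ``a`` and ``b``."""
    ga, gb = table.genes_of(a), table.genes_of(b)
    if not ga:
        raise DomainError(f"disease {a!r} has no associated genes")
    if not gb:
        raise DomainError(f"disease {b!r} has no associated genes")
    return _jaccard(ga, gb)


def gene_similarity(table: AssociationTable, g1: str, g2: str) -> float:
    """Jaccard index of the disease sets of genes ``g1`` and ``g2``."""
    d1, d2 = table.diseases_of(g1), table.diseases_of(g2)
    if not d1:
        raise DomainError(f"gene {g1!r} is not in the table")
    if not d2:
        raise DomainError(f"gene {g2!r} is not in the table")
    return _jaccard(d1, d2)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise disease similarity; diagonal is exactly 1."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DomainError("similarity matrix shape does not match labels")

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class DistanceMatrix:
    """Entrywise ``1 - similarity``; symmetric with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DomainError("distance matrix shape does not match labels")


def build_similarity_matrix(
    table: AssociationTable, diseases: Iterable[str]
) -> SimilarityMatrix:
    """Pairwise Jaccard similarity matrix over the listed diseases.

    Every listed disease must carry at least one gene; a missing disease
    raises :class:`DomainError` naming it.
    """
    labels = list(diseases)
    gene_sets = []
    for d in labels:
        gs = table.genes_of(d)
        if not gs:
            raise DomainError(f"disease {d!r} has no associated genes")
        gene_sets.append(gs)
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _jaccard(gene_sets[i], gene_sets[j])
    return SimilarityMatrix(labels, values)


def to_distance(m: SimilarityMatrix) -> DistanceMatrix:
    """Convert similarity to distance by subtracting each entry from 1."""
    return DistanceMatrix(list(m.labels), 1.0 - m.values)
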