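"""Disease-tree inference: Parent Promotion and a rooted MWST baseline.

Both methods start from the pairwise gene-set distance matrix
(``1 - Jaccard``) over the disease terms and a table of per-disease
PubMed-style citation counts, and output a rooted tree on exactly those
terms.

Parent Promotion first runs complete-linkage agglomerative clustering on
the distances, then converts the dendrogram to a named tree bottom-up:
each cluster carries a single *representative* — the most recently
promoted disease.  When two clusters merge, their two representatives
compete and the one with more citations is promoted: it becomes the
parent of the other representative and represents the merged cluster.  A
disease demoted to child status never competes again, so the final
representative (typically the best-studied, most general term) is the
root.

The MWST baseline builds the minimum-weight spanning tree of the complete
disease graph under the same distances (minimising distance is maximising
similarity), roots it at the most-cited disease, and orients all edges
away from the root.

Tie-breaking is deterministic throughout and documented on each function:
clustering prefers the lexicographically smallest member-id pair, equal
citation counts promote the lexicographically smaller id, and spanning
tree edges are taken in sorted (weight, min(id), max(id)) order.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .associations import (
    AssociationTable,
    DistanceMatrix,
    build_similarity_matrix,
    to_distance,
)
from .exceptions import DomainError
from .reference import Hierarchy

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "CitationTable",
    "read_citations",
    "write_citations",
    "complete_linkage",
    "parent_promotion",
    "mwst_infer",
    "infer",
]


@dataclass
class CitationTable:
    """Non-negative article counts per disease term."""

    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, disease_id: str) -> int:
        try:
            return self.counts[disease_id]
        except KeyError:
            raise DomainError(
                f"no citation count for disease {disease_id!r}"
            ) from None

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.counts


def read_citations(path) -> CitationTable:
    """Read a ``disease_id<TAB>count`` TSV (``#`` lines ignored)."""
    from .exceptions import ParseError

    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            try:
                count = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: count {fields[1]!r} is not an integer"
                ) from None
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative citation count")
            counts[fields[0].strip()] = count
    return CitationTable(counts)


def write_citations(citations: CitationTable, path,
                    header_lines=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for d in sorted(citations.counts):
            fh.write(f"{d}\t{citations.counts[d]}\n")


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    Clusters are integer ids: leaf ``i`` is ``leaves[i]`` for
    ``0 <= i < n``; the ``k``-th merge creates cluster ``n + k``.  Each
    merge records its two input clusters and the inter-cluster distance
    (height) at which they joined.  Complete linkage is monotone, so
    heights are non-decreasing in merge order.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Complete-linkage (max-linkage) agglomerative clustering.

    The inter-cluster distance is the maximum pairwise distance between
    members.  At each step the pair of clusters with minimum distance is
    merged; among ties, the pair whose sorted (smallest-member-id,
    smallest-member-id) key is lexicographically least wins, which makes
    the dendrogram deterministic and independent of input order.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise DomainError("clustering requires at least 2 diseases")

    dist = np.asarray(d.values, dtype=float).copy()
    active: list[int] = list(range(n))  # cluster ids, row i of `dist` ↔ active[i]
    min_label: dict[int, str] = {i: labels[i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        m = len(active)
        # find minimum over strict upper triangle
        iu, ju = np.triu_indices(m, k=1)
        vals = dist[iu, ju]
        best = vals.min()
        # tie-break: lexicographically smallest (min, max) member-id pair
        cand = np.flatnonzero(vals == best)
        best_key = None
        best_pair = None
        for k in cand:
            i, j = int(iu[k]), int(ju[k])
            a, b = min_label[active[i]], min_label[active[j]]
            key = (min(a, b), max(a, b))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair
        new_id = n + step
        merges.append((active[i], active[j], float(best)))
        min_label[new_id] = min(min_label[active[i]], min_label[active[j]])

        # Lance-Williams update for complete linkage: new row is the max
        merged_row = np.maximum(dist[i], dist[j])
        dist[i] = merged_row
        dist[:, i] = merged_row
        dist[i, i] = 0.0
        active[i] = new_id
        dist = np.delete(np.delete(dist, j, axis=0), j, axis=1)
        del active[j]

    return Dendrogram(labels, merges)


def parent_promotion(
    dendrogram: Dendrogram, citations: CitationTable
) -> Hierarchy:
    """Convert a dendrogram into a rooted disease tree by citation counts.

    Processes merges bottom-up.  Each cluster carries one representative;
    a singleton's representative is itself.  At each merge the two
    representatives compete: the one with more citations (ties: the
    lexicographically smaller id) is promoted to parent of the other and
    represents the merged cluster.  The final representative is the root.
    Every edge (p, c) therefore satisfies citations(p) >= citations(c).
    """
    for leaf in dendrogram.leaves:
        if leaf not in citations:
            raise DomainError(f"no citation count for disease {leaf!r}")

    rep: dict[int, str] = {i: d for i, d in enumerate(dendrogram.leaves)}
    n = len(dendrogram.leaves)
    edges: list[tuple[str, str]] = []
    root = dendrogram.leaves[0]
    for k, (left, right, _height) in enumerate(dendrogram.merges):
        a, b = rep[left], rep[right]
        if (citations[a], b) > (citations[b], a):  # more citations wins;
            parent, child = a, b                   # ties: smaller id wins
        else:
            parent, child = b, a
        edges.append((parent, child))
        rep[n + k] = parent
        root = parent

    tree = Hierarchy(list(dendrogram.leaves), edges)
    logger.info("parent promotion: %d terms, root %r", n, root)
    return tree


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[rx] = ry
        return True


def mwst_infer(d: DistanceMatrix, citations: CitationTable) -> Hierarchy:
    """Minimum-weight spanning tree over the complete disease graph.

    Edge weight between two diseases is their distance (1 - similarity),
    so the minimum-weight tree connects diseases by their highest gene-set
    similarities.  Kruskal's algorithm with edges in sorted
    (weight, min(id), max(id)) order makes the result deterministic even
    with the frequent weight ties of sparse gene data.  The tree is rooted
    at the disease with the most citations (ties: lexicographically
    smaller id) and edges are oriented away from the root.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise DomainError("spanning tree requires at least 2 diseases")
    for lab in labels:
        if lab not in citations:
            raise DomainError(f"no citation count for disease {lab!r}")

    edge_pool = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            u, v = (a, b) if a < b else (b, a)
            edge_pool.append((float(d.values[i, j]), u, v))
    edge_pool.sort()

    uf = _UnionFind(labels)
    tree_edges = []
    for w, u, v in edge_pool:
        if uf.union(u, v):
            tree_edges.append((u, v))
            if len(tree_edges) == n - 1:
                break

    root = min(labels, key=lambda x: (-citations[x], x))

    # orient away from the root
    import networkx as nx

    undirected = nx.Graph(tree_edges)
    directed = list(nx.bfs_edges(undirected, root))
    tree = Hierarchy(labels, directed)
    logger.info("mwst: %d terms, root %r", n, root)
    return tree


def infer(
    method: str,
    table: AssociationTable,
    diseases: Sequence[str],
    citations: CitationTable,
) -> Hierarchy:
    """Full pipeline: similarity → distance → tree by the chosen method.

    ``method`` is ``"parent_promotion"`` (alias ``"pp"``) or ``"mwst"``.
    """
    dist = to_distance(build_similarity_matrix(table, diseases))
    if method in ("parent_promotion", "pp"):
        tree = parent_promotion(complete_linkage(dist), citations)
    elif method == "mwst":
        tree = mwst_infer(dist, citations)
    else:
        raise DomainError(f"unknown inference method {method!r}")
    logger.info("inferred tree: method=%s n=%d", method, len(diseases))
    return tree
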