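"""Synthetic taxonomies, gene associations, and citation tables.

The generator emulates the structure the inference methods assume: a
rooted disease tree in which (i) a child's gene set overlaps its parent's
(a tunable inherited fraction plus novel genes), so gene-set Jaccard
similarity carries the clustering signal, and (ii) more general diseases
are better studied, so citation counts strictly decrease with depth and
carry the rooting/promotion signal.  A noise parameter reassigns a
fraction of associations to random diseases, degrading the clustering
signal the way sparse or mislabeled curation would.

:func:`make_separable_fixture` goes further: it constructs gene sets
whose pairwise distances form an exact ultrametric aligned with the
generating tree (equal-size gene sets whose overlap counts the shared
dendrogram clusters), which *guarantees* that complete-linkage clustering
followed by parent promotion reproduces the generating tree edge-for-edge.

All outputs are bit-reproducible from the seed; one random stream is
consumed in the documented order taxonomy → associations → citations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationTable
from .exceptions import ConfigError, DomainError
from .inference import CitationTable
from .reference import Hierarchy

__all__ = [
    "SyntheticConfig",
    "generate_taxonomy",
    "generate_associations",
    "generate_citations",
    "generate_dataset",
    "make_separable_fixture",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults give a mid-sized, clearly clusterable taxonomy: 50 terms at
    fan-out ≤ 3 (MeSH-subtree scale), 5 novel genes per term with 80% of
    the parent set inherited (strong but imperfect nesting), no noise, and
    citation counts decaying geometrically from 10^6 at the root.
    """

    n_terms: int = 50
    max_children: int = 3
    genes_per_term: int = 5
    inherit_fraction: float = 0.8
    noise_swap_rate: float = 0.0
    citation_base: int = 1_000_000
    citation_decay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ConfigError("n_terms must be >= 2")
        if self.max_children < 2:
            raise ConfigError("max_children must be >= 2")
        if self.genes_per_term < 1:
            raise ConfigError("genes_per_term must be >= 1")
        if not 0.0 <= self.inherit_fraction <= 1.0:
            raise ConfigError("inherit_fraction must be in [0, 1]")
        if not 0.0 <= self.noise_swap_rate <= 1.0:
            raise ConfigError("noise_swap_rate must be in [0, 1]")
        if not 0.0 < self.citation_decay < 1.0:
            raise ConfigError("citation_decay must be in (0, 1)")


def _term_id(i: int) -> str:
    return f"T{i:04d}"


def generate_taxonomy(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> Hierarchy:
    """Random rooted tree with ``n_terms`` nodes and out-degree ≤ max_children.

    Nodes are attached one at a time to a uniformly chosen existing node
    that still has spare child capacity.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = [_term_id(i) for i in range(config.n_terms)]
    out_degree = {ids[0]: 0}
    edges = []
    for node in ids[1:]:
        open_slots = sorted(n for n, d in out_degree.items()
                            if d < config.max_children)
        parent = open_slots[rng.integers(len(open_slots))]
        edges.append((parent, node))
        out_degree[parent] += 1
        out_degree[node] = 0
    return Hierarchy(ids, edges)


def _depths(h: Hierarchy) -> dict[str, int]:
    (root,) = h.roots
    depth = {root: 0}
    stack = [root]
    while stack:
        x = stack.pop()
        for c in h.children(x):
            depth[c] = depth[x] + 1
            stack.append(c)
    return depth


def _rewire_noise(
    records: set[tuple[str, str]],
    rate: float,
    diseases: list[str],
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Reassign a fraction of pairs to uniformly random diseases.

    A pair is skipped rather than moved when moving it would leave its
    disease with no genes at all.
    """
    pairs = sorted(records)
    k = int(round(rate * len(pairs)))
    if k == 0:
        return set(records)
    chosen = rng.choice(len(pairs), size=k, replace=False)
    by_disease: dict[str, set[str]] = {}
    for d, g in pairs:
        by_disease.setdefault(d, set()).add(g)
    out = set(records)
    for i in sorted(int(c) for c in chosen):
        d, g = pairs[i]
        if len(by_disease[d]) <= 1:
            continue
        new_d = diseases[rng.integers(len(diseases))]
        out.discard((d, g))
        by_disease[d].discard(g)
        out.add((new_d, g))
        by_disease.setdefault(new_d, set()).add(g)
    return out


def generate_associations(
    h: Hierarchy,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> AssociationTable:
    """Nested gene sets down the tree, then optional random rewiring.

    The root receives ``genes_per_term`` fresh genes; each child inherits
    a sample of ``round(inherit_fraction * |parent set|)`` parent genes
    plus ``genes_per_term`` fresh ones.  ``noise_swap_rate`` of all pairs
    are then reassigned to random diseases (no disease is emptied).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    (root,) = h.roots
    gene_counter = 0

    def fresh(k: int) -> list[str]:
        nonlocal gene_counter
        out = [f"G{gene_counter + i:05d}" for i in range(k)]
        gene_counter += k
        return out

    gene_sets: dict[str, set[str]] = {root: set(fresh(config.genes_per_term))}
    stack = [root]
    while stack:
        x = stack.pop()
        for c in sorted(h.children(x)):
            parent_genes = sorted(gene_sets[x])
            k = int(round(config.inherit_fraction * len(parent_genes)))
            inherited = rng.choice(parent_genes, size=k, replace=False)
            gene_sets[c] = set(inherited) | set(fresh(config.genes_per_term))
            stack.append(c)

    records = {(d, g) for d, genes in gene_sets.items() for g in genes}
    records = _rewire_noise(
        records, config.noise_swap_rate, sorted(h.nodes), rng
    )
    return AssociationTable(records)


def generate_citations(
    h: Hierarchy,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> CitationTable:
    """Citation counts decaying geometrically with depth, plus jitter.

    Depth-d nodes get ``round(citation_base * citation_decay^d)`` plus a
    non-negative jitter bounded so that every depth-d count stays strictly
    above every depth-(d+1) count; counts therefore strictly decrease
    along every root-to-leaf path and the root holds the unique maximum.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if len(h.roots) != 1:
        raise DomainError("generate_citations requires a single-rooted tree")
    depth = _depths(h)
    max_depth = max(depth.values())
    base = [
        int(round(config.citation_base * config.citation_decay**d))
        for d in range(max_depth + 1)
    ]
    for d in range(max_depth):
        if base[d] <= base[d + 1]:
            raise ConfigError(
                "citation_base too small to keep counts strictly "
                f"decreasing between depths {d} and {d + 1}"
            )
    counts: dict[str, int] = {}
    for x in sorted(h.nodes):
        d = depth[x]
        jitter_max = base[d - 1] - base[d] - 1 if d > 0 else 0
        counts[x] = base[d] + int(rng.integers(jitter_max + 1)) if jitter_max > 0 else base[d]
    return CitationTable(counts)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[Hierarchy, AssociationTable, CitationTable]:
    """Taxonomy, associations and citations from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    h = generate_taxonomy(config, rng)
    table = generate_associations(h, config, rng)
    citations = generate_citations(h, config, rng)
    return h, table, citations


def make_separable_fixture(
    n_terms: int, seed: int, noise: float = 0.0
) -> tuple[Hierarchy, AssociationTable, CitationTable]:
    """A fixture on which parent promotion provably recovers the tree.

    Gene sets are built from shared pools attached to the clusters of the
    dendrogram that would reconstruct the tree (each node plus one child
    subtree after another), padded with private genes to a common size s.
    For any two terms the gene overlap then equals the number of
    dendrogram clusters containing both, so Jaccard distance
    ``1 - o/(2s - o)`` is an exact ultrametric whose dendrogram is the
    intended one: complete linkage reproduces it, heights strictly
    increase along every nesting chain, and the only ties are between
    disjoint clusters, where merge order cannot change the result.
    Citations strictly decrease with depth, so each merge promotes the
    true parent.  With ``noise`` > 0 the associations are randomly
    rewired afterwards and recovery is no longer guaranteed.
    """
    if n_terms < 2:
        raise ConfigError("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(n_terms=n_terms, max_children=3, seed=seed)
    h = generate_taxonomy(config, rng)
    (root,) = h.roots

    gene_counter = 0

    def fresh() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:05d}"

    gene_sets: dict[str, set[str]] = {x: set() for x in h.nodes}

    def fold(x: str) -> list[str]:
        # bottom-up: attach one shared gene to each cluster
        # {x} ∪ subtree(c1) ∪ ... ∪ subtree(ci) as it forms
        members = [x]
        for c in sorted(h.children(x)):
            members.extend(fold(c))
            g = fresh()
            for m in members:
                gene_sets[m].add(g)
        return members

    fold(root)

    size = max(len(s) for s in gene_sets.values()) + 1
    for x in sorted(gene_sets):
        while len(gene_sets[x]) < size:
            gene_sets[x].add(fresh())

    records = {(d, g) for d, genes in gene_sets.items() for g in genes}
    if noise > 0.0:
        records = _rewire_noise(records, noise, sorted(h.nodes), rng)
    table = AssociationTable(records)

    depth = _depths(h)
    citations = CitationTable(
        {x: 1_000_000 - 1_000 * depth[x] for x in h.nodes}
    )
    return h, table, citations
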