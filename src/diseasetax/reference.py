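"""Reference disease hierarchies: parsing, pruning, and queries.

A :class:`Hierarchy` is a rooted DAG (or forest) of disease terms with
parent→child edges.  Two reference formats are supported:

* OBO 1.2 flat files (Disease Ontology style): each ``is_a`` assertion
  child-is_a-parent becomes one parent→child edge; obsolete terms are
  skipped and synonyms are kept in a side map.
* MeSH-style tree-number tables: a TSV of ``term_name<TAB>tree_number``
  rows where dotted position codes (e.g. ``C08.381.742``) encode the
  forest.  A name occurring at several positions is merged into a single
  node, turning the tree into a DAG.

Because similarity is undefined for diseases without gene annotations,
:func:`prune_and_reconnect` removes geneless terms while re-wiring each
retained node to its nearest retained proper ancestors, so that
ancestor/descendant reachability among retained terms is exactly preserved.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import networkx as nx

from .associations import AssociationTable
from .exceptions import LookupError_, ParseError, SizeError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "Hierarchy",
    "read_obo",
    "read_mesh_trees",
    "read_edge_list",
    "write_edge_list",
    "prune_and_reconnect",
    "extract_subnetwork",
    "ancestors",
]


class Hierarchy:
    """A rooted DAG/forest of terms with parent→child edges.

    Nodes carry an id and a display name (defaulting to the id).  Edge
    direction is parent→child throughout the package.
    """

    def __init__(
        self,
        nodes: Iterable[str] | Iterable[tuple[str, str]] = (),
        edges: Iterable[tuple[str, str]] = (),
        synonyms: dict[str, list[str]] | None = None,
    ):
        self.graph = nx.DiGraph()
        for node in nodes:
            if isinstance(node, tuple):
                node_id, name = node
            else:
                node_id, name = node, node
            self.graph.add_node(node_id, name=name)
        for parent, child in edges:
            if parent == child:
                raise StructuralError(f"self-loop on {parent!r}")
            if parent not in self.graph or child not in self.graph:
                raise StructuralError(
                    f"edge ({parent!r}, {child!r}) references an undeclared node"
                )
            self.graph.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise StructuralError(f"hierarchy contains a cycle: {cycle}")
        self.synonyms: dict[str, list[str]] = synonyms or {}

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph if self.graph.in_degree(n) == 0}

    def name_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id].get("name", node_id)

    def parents(self, node_id: str) -> set[str]:
        return set(self.graph.predecessors(node_id))

    def children(self, node_id: str) -> set[str]:
        return set(self.graph.successors(node_id))

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hierarchy):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Hierarchy: {len(self)} nodes, {self.graph.number_of_edges()} "
            f"edges, {len(self.roots)} roots>"
        )


def ancestors(h: Hierarchy, x: str) -> set[str]:
    """All proper ancestors of ``x`` (transitive; excludes ``x`` itself)."""
    if x not in h:
        raise LookupError_(f"term {x!r} not in hierarchy")
    return nx.ancestors(h.graph, x)


def descendants(h: Hierarchy, x: str) -> set[str]:
    """All proper descendants of ``x``."""
    if x not in h:
        raise LookupError_(f"term {x!r} not in hierarchy")
    return nx.descendants(h.graph, x)


# -- OBO ---------------------------------------------------------------


def read_obo(path) -> Hierarchy:
    """Parse an OBO 1.2 flat file into a Hierarchy.

    Only the tags ``id``, ``name``, ``is_a``, ``synonym`` and
    ``is_obsolete`` are interpreted.  The ``is_a`` direction is inverted:
    ``c is_a p`` yields the edge (p, c).  Obsolete terms (and edges
    touching them) are dropped.  An ``is_a`` target that is never declared
    as a term raises :class:`StructuralError`.
    """
    terms: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    is_a: list[tuple[str, str]] = []  # (parent, child)

    cur_id: str | None = None
    cur_name: str | None = None
    cur_parents: list[str] = []
    cur_syns: list[str] = []
    cur_obsolete = False
    in_term = False

    def flush() -> None:
        nonlocal cur_id, cur_name, cur_parents, cur_syns, cur_obsolete
        if in_term and cur_id is not None and not cur_obsolete:
            terms[cur_id] = cur_name if cur_name is not None else cur_id
            if cur_syns:
                synonyms[cur_id] = list(cur_syns)
            for p in cur_parents:
                is_a.append((p, cur_id))
        cur_id = cur_name = None
        cur_parents, cur_syns = [], []
        cur_obsolete = False

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line or line.startswith("!"):
                continue
            if ":" not in line:
                continue
            tag, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            tag = tag.strip()
            if tag == "id":
                cur_id = value
            elif tag == "name":
                cur_name = value
            elif tag == "is_a":
                cur_parents.append(value.split()[0])
            elif tag == "synonym":
                # synonym: "text" SCOPE [xrefs] -- keep the quoted text
                if value.startswith('"') and value.count('"') >= 2:
                    cur_syns.append(value.split('"')[1])
                else:
                    cur_syns.append(value)
            elif tag == "is_obsolete" and value.lower() == "true":
                cur_obsolete = True
    flush()

    edges = []
    for parent, child in is_a:
        if parent not in terms:
            if child in terms:
                raise StructuralError(
                    f"is_a target {parent!r} of {child!r} is not a declared term"
                )
            continue  # child obsolete; edge dropped with it
        edges.append((parent, child))

    h = Hierarchy(list(terms.items()), edges, synonyms=synonyms)
    logger.info(
        "read OBO %s: %d terms, %d is_a edges, %d roots",
        path, len(h), len(h.edges), len(h.roots),
    )
    return h


# -- MeSH tree numbers -------------------------------------------------


def read_mesh_trees(path) -> Hierarchy:
    """Parse a ``term_name<TAB>tree_number`` TSV into a Hierarchy.

    Tree numbers are dotted position codes; a row's parent is the row
    owning the prefix obtained by dropping the last dotted component.
    A name appearing at several positions becomes a single node (the MeSH
    duplicate-name merge), which can give the node several parents.  A
    merge that would create a self-loop drops the edge with a warning; a
    longer cycle (a name both above and below another) is a structural
    error because hierarchies must stay acyclic.
    """
    position_to_name: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
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
            name, tree_number = fields[0].strip(), fields[1].strip()
            parts = tree_number.split(".")
            if not name or any(not p for p in parts):
                raise ParseError(
                    f"{path}:{lineno}: malformed row {line!r}"
                )
            position_to_name[tree_number] = name
            rows.append((name, tree_number))

    names = {name for name, _ in rows}
    edges: set[tuple[str, str]] = set()
    for name, tree_number in rows:
        if "." not in tree_number:
            continue  # top of a tree: a root unless the name recurs deeper
        prefix = tree_number.rsplit(".", 1)[0]
        parent = position_to_name.get(prefix)
        if parent is None:
            continue  # orphan prefix: this row starts a new root
        if parent == name:
            logger.warning(
                "dropping self-loop on %r created by duplicate-name merge", name
            )
            continue
        edges.add((parent, name))
    h = Hierarchy(sorted(names), sorted(edges))
    logger.info(
        "read MeSH trees %s: %d rows, %d distinct names, %d edges",
        path, len(rows), len(h), len(h.edges),
    )
    return h


# -- edge-list TSV -----------------------------------------------------


def read_edge_list(path) -> Hierarchy:
    """Read a ``parent_id<TAB>child_id`` edge list (``#`` lines ignored)."""
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                nodes.add(fields[0].strip())  # isolated node
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 1 or 2 tab-separated columns"
                )
            p, c = fields[0].strip(), fields[1].strip()
            nodes.update((p, c))
            edges.append((p, c))
    return Hierarchy(sorted(nodes), edges)


def write_edge_list(h: Hierarchy, path, header_lines: Iterable[str] = ()) -> None:
    """Write a Hierarchy as a ``parent<TAB>child`` TSV with ``#`` headers.

    Isolated nodes are written as single-column rows so the node universe
    round-trips.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for parent, child in sorted(h.edges):
            fh.write(f"{parent}\t{child}\n")
        connected = {n for e in h.edges for n in e}
        for node in sorted(h.nodes - connected):
            fh.write(f"{node}\n")


# -- pruning -----------------------------------------------------------


def prune_and_reconnect(h: Hierarchy, table: AssociationTable) -> Hierarchy:
    """Drop geneless terms, reconnecting across the deleted ones.

    The retained node set is exactly the terms with ≥1 associated gene.
    A retained node's new parents are its nearest retained proper
    ancestors: edge (p, x) exists iff some original path p→…→x passes
    through no other retained node.  This preserves reachability among
    retained nodes and is idempotent.  Retained descendants of deleted
    roots become roots.
    """
    retained = {n for n in h.nodes if table.genes_of(n)}
    if not retained:
        logger.warning("prune_and_reconnect: no term has gene annotations")

    # For a deleted node d, the nearest retained ancestors reachable by
    # walking up through deleted nodes only; memoised, safe because h is
    # acyclic.
    memo: dict[str, set[str]] = {}

    def nearest_retained_above(node: str) -> set[str]:
        if node in memo:
            return memo[node]
        result: set[str] = set()
        for p in h.parents(node):
            if p in retained:
                result.add(p)
            else:
                result |= nearest_retained_above(p)
        memo[node] = result
        return result

    edges: set[tuple[str, str]] = set()
    for x in retained:
        for p in nearest_retained_above(x):
            edges.add((p, x))

    pruned = Hierarchy(
        [(n, h.name_of(n)) for n in sorted(retained)], sorted(edges)
    )
    logger.info(
        "pruned %d geneless of %d terms; %d retained, %d edges",
        len(h) - len(retained), len(h), len(retained), len(edges),
    )
    return pruned


# -- subnetwork extraction ---------------------------------------------


def extract_subnetwork(
    h: Hierarchy, root_name: str, min_descendants: int
) -> Hierarchy:
    """Induced sub-DAG on a named root and all of its descendants.

    Name matching is exact and case-sensitive.  If fewer than
    ``min_descendants`` proper descendants exist, a :class:`SizeError`
    carrying the actual count is raised.
    """
    matches = [n for n in h.nodes if h.name_of(n) == root_name]
    if not matches:
        raise LookupError_(f"no term named {root_name!r}")
    if len(matches) > 1:
        raise LookupError_(f"term name {root_name!r} is ambiguous: {matches}")
    root = matches[0]
    desc = descendants(h, root)
    if len(desc) < min_descendants:
        raise SizeError(
            f"{root_name!r} has {len(desc)} descendants, "
            f"fewer than the required {min_descendants}",
            count=len(desc),
        )
    keep = desc | {root}
    sub = h.graph.subgraph(keep)
    return Hierarchy(
        [(n, h.name_of(n)) for n in sorted(keep)], sorted(sub.edges)
    )
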