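"""Background networks: readers, builders, and the interactor browser.

A :class:`BackgroundNetwork` is a simple undirected graph over normalized
gene symbols — no self-loops, no parallel edges — optionally edge-weighted,
tagged by origin (protein–protein interaction, co-expression thresholding,
co-annotation, or custom).  It wraps a :class:`networkx.Graph`.

Builders:

* :func:`read_network` — SIF edge lists (``nodeA<TAB>relation<TAB>nodeB``;
  a single-field row denotes an isolated node, as Cytoscape accepts) and
  weighted pair tables (``nodeA<TAB>nodeB<TAB>weight``).
* :func:`build_coexpression_network` — threshold a weighted gene-pair table;
  duplicate pairs keep the maximum weight before thresholding.
* :func:`build_coannotation_network` — connect genes that co-appear in the
  sets of a gene-set library.  Co-appearance is scored as the Jaccard index
  over set membership (shared sets / sets containing either gene), a
  similarity in [0, 1]; the corresponding distance is 1 - similarity.

:func:`neighbors` implements the recursive direct-interactor browser: a
breadth-limited expansion tree around one gene, each node annotated with its
background degree, previously visited nodes marked but not re-expanded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import DataError
from .genesets import GeneList, GeneSetLibrary, normalize_symbol

__all__ = [
    "BackgroundNetwork",
    "NeighborNode",
    "read_network",
    "write_sif_network",
    "build_coexpression_network",
    "coannotation_score",
    "build_coannotation_network",
    "neighbors",
    "to_gene_list",
]

NETWORK_KINDS = ("ppi", "coexpression", "coannotation", "custom")


@dataclass
class BackgroundNetwork:
    """Simple undirected graph over gene symbols, optionally edge-weighted."""

    graph: nx.Graph
    kind: str = "custom"
    self_loops_dropped: int = 0
    duplicate_edges_merged: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise DataError(f"unknown network kind {self.kind!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, symbol: str) -> bool:
        return self.graph.has_node(symbol)

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def degree(self, symbol: str) -> int:
        return int(self.graph.degree[symbol])

    def neighbors_of(self, symbol: str) -> list[str]:
        return sorted(self.graph.neighbors(symbol))


def _add_edge(g: nx.Graph, u: str, v: str, **attrs) -> tuple[int, int]:
    """Add an undirected edge; returns (self_loops_dropped, duplicates_merged)."""
    if u == v:
        return 1, 0
    dup = 1 if g.has_edge(u, v) else 0
    g.add_edge(u, v, **attrs)
    return 0, dup


def read_network(path: str | Path, dialect: str = "sif", kind: str = "custom") -> BackgroundNetwork:
    """Read a network file.

    ``sif``: rows ``nodeA<TAB>relation<TAB>nodeB`` (additional trailing node
    fields are accepted, Cytoscape-style, each forming an edge; a row with a
    single field declares an isolated node).  ``tsv-weighted``: rows
    ``nodeA<TAB>nodeB<TAB>weight``; a header row is auto-detected by a
    non-numeric third field in row 1.  Symbols are normalized; duplicate and
    reversed-duplicate edges are merged and self-loops dropped, with counters
    kept on the returned network.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv-weighted"):
        raise DataError(f"unknown network dialect {dialect!r}")
    g: nx.Graph = nx.Graph()
    loops = dups = 0
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            ctx = f"{path.name} row {lineno}"
            if dialect == "sif":
                if len(fields) == 1:
                    g.add_node(normalize_symbol(fields[0], context=ctx))
                    continue
                if len(fields) == 2:
                    raise DataError(f"row {lineno}: expected 1 or >= 3 fields in SIF")
                relation = fields[1].strip()
                u = normalize_symbol(fields[0], context=ctx)
                for raw in fields[2:]:
                    if not raw.strip():
                        continue
                    v = normalize_symbol(raw, context=ctx)
                    dl, dd = _add_edge(g, u, v, relation=relation)
                    loops += dl
                    dups += dd
            else:
                if len(fields) != 3:
                    raise DataError(f"row {lineno}: expected 3 fields")
                if lineno == 1 and not _is_number(fields[2]):
                    continue  # header row
                if not _is_number(fields[2]):
                    raise DataError(f"row {lineno}: non-numeric weight {fields[2]!r}")
                u = normalize_symbol(fields[0], context=ctx)
                v = normalize_symbol(fields[1], context=ctx)
                w = float(fields[2])
                if u == v:
                    loops += 1
                    continue
                if g.has_edge(u, v):
                    dups += 1
                    # keep the maximum weight for duplicate pairs
                    w = max(w, g.edges[u, v].get("weight", w))
                g.add_edge(u, v, weight=w)
    return BackgroundNetwork(graph=g, kind=kind, self_loops_dropped=loops, duplicate_edges_merged=dups)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_sif_network(net: BackgroundNetwork, path: str | Path, default_relation: str = "pp") -> Path:
    """Write a network in SIF format.

    Each unordered edge is written once with endpoints in lexicographic
    order, rows sorted; isolated nodes are written as single-field rows so
    that re-reading reproduces the (nodes, edges) pair exactly.
    """
    path = Path(path)
    rows = []
    for u, v, attrs in net.graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append(f"{a}\t{attrs.get('relation', default_relation)}\t{b}")
    rows.sort()
    isolated = sorted(n for n in net.graph.nodes if net.graph.degree[n] == 0)
    path.write_text("".join(r + "\n" for r in rows + isolated), encoding="utf-8")
    return path


def build_coexpression_network(
    pairs: str | Path | Iterable[tuple[str, str, float]],
    cutoff: float,
) -> BackgroundNetwork:
    """Threshold a weighted gene-pair table into a co-expression network.

    ``pairs`` is a path to a 3-column TSV or an iterable of
    ``(gene, gene, weight)`` tuples.  An edge is kept iff its weight is
    >= ``cutoff``; duplicate pairs keep the maximum weight before
    thresholding; self-pairs are dropped.
    """
    if isinstance(pairs, (str, Path)):
        full = read_network(pairs, dialect="tsv-weighted", kind="coexpression")
    else:
        g: nx.Graph = nx.Graph()
        loops = dups = 0
        for u_raw, v_raw, w in pairs:
            u, v = normalize_symbol(str(u_raw)), normalize_symbol(str(v_raw))
            w = float(w)
            if u == v:
                loops += 1
                continue
            if g.has_edge(u, v):
                dups += 1
                w = max(w, g.edges[u, v]["weight"])
            g.add_edge(u, v, weight=w)
        full = BackgroundNetwork(g, kind="coexpression", self_loops_dropped=loops,
                                 duplicate_edges_merged=dups)
    kept = nx.Graph()
    kept.add_nodes_from(full.graph.nodes)
    for u, v, attrs in full.graph.edges(data=True):
        if attrs["weight"] >= cutoff:
            kept.add_edge(u, v, weight=attrs["weight"])
    return BackgroundNetwork(
        kept,
        kind="coexpression",
        self_loops_dropped=full.self_loops_dropped,
        duplicate_edges_merged=full.duplicate_edges_merged,
    )


def _membership(lib: GeneSetLibrary) -> dict[str, frozenset[int]]:
    member: dict[str, set[int]] = {}
    for i, gl in enumerate(lib):
        for g in gl.genes:
            member.setdefault(g, set()).add(i)
    return {g: frozenset(s) for g, s in member.items()}


def coannotation_score(u: str, v: str, lib: GeneSetLibrary) -> float:
    """Co-appearance level of two genes across a library's sets.

    Jaccard index over set membership: |sets containing both| / |sets
    containing either|.  Symmetric, in [0, 1]; 1 when the genes appear in
    exactly the same sets (and at least one), 0 when they share no set or
    neither is annotated.
    """
    if len(lib) == 0:
        raise DataError("library is empty")
    member = _membership(lib)
    su = member.get(normalize_symbol(u), frozenset())
    sv = member.get(normalize_symbol(v), frozenset())
    either = len(su | sv)
    if either == 0:
        return 0.0
    return len(su & sv) / either


def build_coannotation_network(lib: GeneSetLibrary, cutoff: float) -> BackgroundNetwork:
    """Connect every gene pair whose co-annotation score is >= ``cutoff``.

    The cutoff is inclusive and must lie in [0, 1].  At cutoff 0 every pair
    of universe genes qualifies (score 0 >= 0), giving the complete graph;
    meaningful networks use a positive cutoff.  Edge weights carry the score.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise DataError(f"co-annotation cutoff must lie in [0, 1], got {cutoff}")
    g: nx.Graph = nx.Graph()
    genes = sorted(lib.universe)
    g.add_nodes_from(genes)
    member = _membership(lib)
    if cutoff <= 0.0:
        for u, v in itertools.combinations(genes, 2):
            su, sv = member[u], member[v]
            score = len(su & sv) / len(su | sv)
            g.add_edge(u, v, weight=score)
    else:
        # only pairs sharing >= 1 set can reach a positive score
        for gl in lib:
            for u, v in itertools.combinations(sorted(gl.genes), 2):
                if g.has_edge(u, v):
                    continue
                su, sv = member[u], member[v]
                score = len(su & sv) / len(su | sv)
                if score >= cutoff:
                    g.add_edge(u, v, weight=score)
    return BackgroundNetwork(g, kind="coannotation")


@dataclass
class NeighborNode:
    """A node of the interactor-browser expansion tree.

    ``degree`` is the node's degree in the background network.  ``revisit``
    marks a node already reached elsewhere in the tree; such nodes are
    displayed but not re-expanded.
    """

    symbol: str
    degree: int
    revisit: bool = False
    children: list["NeighborNode"] = field(default_factory=list)

    def walk(self) -> Iterator["NeighborNode"]:
        """Breadth-first traversal of the tree (discovery order)."""
        queue = [self]
        while queue:
            node = queue.pop(0)
            yield node
            queue.extend(node.children)


def neighbors(gene: str, net: BackgroundNetwork, depth: int = 1) -> NeighborNode:
    """Breadth-limited interactor expansion around one gene.

    Level 1 holds the direct interactors, level d the interactors of level
    d-1 nodes.  Children are listed in lexicographic order; a node already
    visited elsewhere is marked ``revisit`` and not expanded again.
    """
    if depth < 1:
        raise DataError("depth must be >= 1")
    sym = normalize_symbol(gene)
    if sym not in net:
        raise DataError(f"gene {sym!r} is not in the network")
    root = NeighborNode(symbol=sym, degree=net.degree(sym))
    visited = {sym}
    frontier = [root]
    for _ in range(depth):
        next_frontier: list[NeighborNode] = []
        for node in frontier:
            for nb in net.neighbors_of(node.symbol):
                child = NeighborNode(symbol=nb, degree=net.degree(nb), revisit=nb in visited)
                node.children.append(child)
                if not child.revisit:
                    visited.add(nb)
                    next_frontier.append(child)
        frontier = next_frontier
    return root


def to_gene_list(obj: NeighborNode | BackgroundNetwork, name: str | None = None) -> GeneList:
    """Collect the nodes of a tree or network as a GeneList.

    Trees yield breadth-first discovery order (revisited duplicates
    skipped); networks yield node insertion order.
    """
    if isinstance(obj, NeighborNode):
        genes: list[str] = []
        seen: set[str] = set()
        for node in obj.walk():
            if node.symbol not in seen:
                seen.add(node.symbol)
                genes.append(node.symbol)
        return GeneList(name=name or f"{obj.symbol}_interactors", genes=tuple(genes))
    if isinstance(obj, BackgroundNetwork):
        return GeneList(name=name or "network_nodes", genes=tuple(obj.graph.nodes))
    raise TypeError(f"cannot convert {type(obj).__name__} to a GeneList")
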