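"""The "network of lists": lists as nodes, significant overlaps as edges.

Nodes are user (input) lists and the library gene sets they significantly
overlap; an edge marks a pairwise overlap whose Bonferroni-corrected Fisher
p-value is below alpha (default 0.05, strict inequality).  Library-set nodes
are classed by overlap multiplicity: ``single_overlap`` when significant
against exactly one input list, ``multi_overlap`` when against two or more;
library sets with no significant edge are absent from the network.  Input
lists always keep class ``input``, and may optionally be connected to each
other when their own pairwise overlap is significant (Bonferroni over the
number of user-list pairs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .errors import DataError
from .enrichment import bonferroni, fisher_overlap, overlap_matrix
from .genesets import GeneList, GeneSetLibrary

__all__ = ["ListsNetwork", "build_lists_network", "export_lists_network"]

NODE_CLASSES = ("input", "single_overlap", "multi_overlap")


@dataclass
class ListsNetwork:
    """Graph of lists: node attribute ``class``; edge attributes ``k``,
    ``p_raw``, ``p_bonferroni``."""

    graph: nx.Graph
    alpha: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, label: str) -> str:
        return self.graph.nodes[label]["class"]

    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


def build_lists_network(
    users: Sequence[GeneList],
    library: GeneSetLibrary,
    alpha: float = 0.05,
    include_user_user_edges: bool = True,
    universe_policy: str = "library",
) -> ListsNetwork:
    """Build the network of lists at significance level ``alpha``.

    The overlap matrix is computed with per-column Bonferroni correction;
    (user, library-set) edges with corrected p < alpha are kept.  When
    ``include_user_user_edges`` is set, every user-list pair is likewise
    Fisher-tested against the same universe, corrected over the number of
    pairs, and connected when significant.
    """
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must lie in (0, 1), got {alpha}")
    users = list(users)
    matrix = overlap_matrix(users, library, universe_policy=universe_policy)
    collisions = set(matrix.user_labels) & set(library.names)
    if collisions:
        raise DataError(f"user list and library set share a label: {sorted(collisions)}")

    g = nx.Graph()
    for ul in users:
        g.add_node(ul.name, **{"class": "input"})
    for user_label in matrix.user_labels:
        for set_label in matrix.set_labels:
            p_corr = float(matrix.p_bonferroni.loc[set_label, user_label])
            if p_corr < alpha:
                cell = matrix.cells[(set_label, user_label)]
                if set_label not in g:
                    g.add_node(set_label)
                g.add_edge(
                    user_label, set_label,
                    k=cell.k, p_raw=cell.p_raw, p_bonferroni=p_corr,
                )

    if include_user_user_edges and len(users) >= 2:
        pairs = list(itertools.combinations(users, 2))
        tests = [fisher_overlap(a, b, matrix.universe) for a, b in pairs]
        corrected = bonferroni([t.p_raw for t in tests])
        for (a, b), t, p_corr in zip(pairs, tests, corrected):
            if p_corr < alpha:
                g.add_edge(a.name, b.name, k=t.k, p_raw=t.p_raw, p_bonferroni=float(p_corr))

    user_labels = {ul.name for ul in users}
    for node in g.nodes:
        if node in user_labels:
            continue
        n_inputs = sum(1 for nb in g.neighbors(node) if nb in user_labels)
        g.nodes[node]["class"] = "multi_overlap" if n_inputs >= 2 else "single_overlap"
    return ListsNetwork(graph=g, alpha=alpha)


def export_lists_network(netl: ListsNetwork, path: str | Path, format: str = "graphml") -> Path:
    """Write the network of lists to disk.

    ``graphml`` carries the node class and edge statistics as attributes
    (ready for Cytoscape import); ``sif`` writes edges with relation
    ``overlaps`` plus two sidecar tables, ``<path>.nodes.tsv`` (node, class)
    and ``<path>.edges.tsv`` (nodeA, nodeB, k, p_raw, p_bonferroni), in
    deterministic row order.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(netl.graph, path)
        return path
    if format == "sif":
        rows = []
        edge_rows = []
        for u, v, attrs in netl.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(f"{a}\toverlaps\t{b}")
            edge_rows.append(
                f"{a}\t{b}\t{attrs['k']}\t{attrs['p_raw']:.6g}\t{attrs['p_bonferroni']:.6g}"
            )
        rows.sort()
        edge_rows.sort()
        isolated = sorted(n for n in netl.graph.nodes if netl.graph.degree[n] == 0)
        path.write_text("".join(r + "\n" for r in rows + isolated), encoding="utf-8")
        nodes_path = path.with_name(path.name + ".nodes.tsv")
        node_rows = [f"{n}\t{netl.graph.nodes[n]['class']}" for n in sorted(netl.graph.nodes)]
        nodes_path.write_text("node\tclass\n" + "".join(r + "\n" for r in node_rows), encoding="utf-8")
        edges_path = path.with_name(path.name + ".edges.tsv")
        edges_path.write_text(
            "nodeA\tnodeB\tk\tp_raw\tp_bonferroni\n" + "".join(r + "\n" for r in edge_rows),
            encoding="utf-8",
        )
        return path
    raise DataError(f"unknown export format {format!r}; expected 'graphml' or 'sif'")
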