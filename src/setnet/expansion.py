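"""Expand a seed gene list into a connecting subnetwork.

Seeds are the input-list genes present in a background network.  For every
unordered seed pair whose shortest-path distance d satisfies
2 <= d <= ``max_steps``, ALL shortest paths of length d are enumerated;
their interior (non-seed) nodes are candidate intermediates.  Each candidate
is scored by *specificity* — the fraction of its background-network links
that go to seed nodes:

    specificity(v) = |neighbors(v) ∩ seeds| / degree(v)

Candidates below the specificity cutoff are removed together with every
path that traverses them (paths are not re-grown).  Direct seed–seed
background edges are always included.  The subnetwork's edge set is the
union of edges on admitted paths plus those seed–seed edges — edges among
intermediates that lie on no admitted path are not added.

Admitted intermediates are ranked by descending (subnetwork link count /
background degree), ties broken by descending subnetwork link count, then
label, and the whole subnetwork can be converted back into a gene list
(seeds first, then intermediates in rank order) or exported as SIF with a
node-attribute sidecar for Cytoscape.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DataError
from .genesets import GeneList
from .networks import BackgroundNetwork

__all__ = [
    "ExpansionParams",
    "Intermediate",
    "Subnetwork",
    "specificity",
    "expand",
    "rank_intermediates",
    "subnetwork_to_list",
    "write_sif",
]


@dataclass(frozen=True)
class ExpansionParams:
    """Knobs of the expansion: path-length ceiling and admission threshold.

    ``max_steps`` is the maximum shortest-path length in links between a
    seed pair (>= 1); ``specificity_cutoff`` in [0, 1] is the minimum
    specificity for admitting an intermediate (inclusive).
    """

    max_steps: int = 2
    specificity_cutoff: float = 0.0

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise DataError("max_steps must be >= 1")
        if not 0.0 <= self.specificity_cutoff <= 1.0:
            raise DataError("specificity_cutoff must lie in [0, 1]")


@dataclass
class Intermediate:
    """An admitted non-seed node with its scores and rank."""

    symbol: str
    specificity: float
    seed_links: int
    subnetwork_links: int
    background_degree: int
    rank: int = 0

    @property
    def ratio(self) -> float:
        return self.subnetwork_links / self.background_degree


@dataclass
class Subnetwork:
    """Result of expanding a seed list over a background network."""

    name: str
    seeds: tuple[str, ...]
    missing_seeds: tuple[str, ...]
    intermediates: dict[str, Intermediate]
    graph: nx.Graph
    params: ExpansionParams
    seed_order: tuple[str, ...] = field(default=())  # original input order incl. missing

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def ranked_intermediates(self) -> list[Intermediate]:
        return sorted(self.intermediates.values(), key=lambda im: im.rank)


def specificity(v: str, seeds: set[str] | frozenset[str], net: BackgroundNetwork) -> float:
    """Fraction of v's background links that go to seed nodes."""
    if v not in net:
        raise DataError(f"node {v!r} is not in the network")
    deg = net.degree(v)
    if deg == 0:
        raise DataError(f"specificity undefined for isolated node {v!r}")
    return len(set(net.graph.neighbors(v)) & set(seeds)) / deg


def expand(seed_list: GeneList, net: BackgroundNetwork, params: ExpansionParams) -> Subnetwork:
    """Connect the seed list through the background network.

    Deterministic for fixed input.  Seeds absent from the network are
    reported on the result (and retained by :func:`subnetwork_to_list`) but
    excluded from path finding; a seed list entirely absent from the network
    is an error.  Seed pairs farther apart than ``max_steps`` are left
    unconnected.
    """
    present = tuple(g for g in seed_list.genes if g in net)
    missing = tuple(g for g in seed_list.genes if g not in net)
    if seed_list.genes and not present:
        raise DataError(
            "no seed is present in the background network; missing: " + ", ".join(missing)
        )
    seed_set = set(present)
    sub = nx.Graph()
    sub.add_nodes_from(present)
    # direct seed-seed background edges are always included
    for u, v in itertools.combinations(present, 2):
        if net.graph.has_edge(u, v):
            sub.add_edge(u, v)

    # enumerate all shortest paths per seed pair with 2 <= d <= max_steps
    paths: list[list[str]] = []
    candidates: set[str] = set()
    for u, v in itertools.combinations(present, 2):
        try:
            d = nx.shortest_path_length(net.graph, u, v)
        except nx.NetworkXNoPath:
            continue
        if 2 <= d <= params.max_steps:
            for path in nx.all_shortest_paths(net.graph, u, v):
                paths.append(path)
                candidates.update(w for w in path[1:-1] if w not in seed_set)

    spec = {w: specificity(w, seed_set, net) for w in candidates}
    admitted_nodes: set[str] = set()
    for path in paths:
        interior = [w for w in path[1:-1] if w not in seed_set]
        if all(spec[w] >= params.specificity_cutoff for w in interior):
            admitted_nodes.update(interior)
            nx.add_path(sub, path)

    intermediates: dict[str, Intermediate] = {}
    for w in admitted_nodes:
        intermediates[w] = Intermediate(
            symbol=w,
            specificity=spec[w],
            seed_links=len(set(net.graph.neighbors(w)) & seed_set),
            subnetwork_links=int(sub.degree[w]),
            background_degree=net.degree(w),
        )
    for rank, im in enumerate(
        sorted(
            intermediates.values(),
            key=lambda im: (-im.ratio, -im.subnetwork_links, im.symbol),
        ),
        start=1,
    ):
        im.rank = rank
    return Subnetwork(
        name=seed_list.name,
        seeds=present,
        missing_seeds=missing,
        intermediates=intermediates,
        graph=sub,
        params=params,
        seed_order=seed_list.genes,
    )


def rank_intermediates(sub: Subnetwork, net: BackgroundNetwork | None = None) -> pd.DataFrame:
    """Ordered table of intermediates: counts, ratio and rank.

    Sorted by descending subnetwork-links / background-degree ratio, ties by
    descending subnetwork link count, then label.  ``net`` is accepted for
    symmetry with :func:`expand` but the counts are already stored on the
    subnetwork.
    """
    records = [
        {
            "intermediate": im.symbol,
            "specificity": im.specificity,
            "seed_links": im.seed_links,
            "subnetwork_links": im.subnetwork_links,
            "background_degree": im.background_degree,
            "ratio": im.ratio,
            "rank": im.rank,
        }
        for im in sub.ranked_intermediates()
    ]
    return pd.DataFrame.from_records(
        records,
        columns=[
            "intermediate",
            "specificity",
            "seed_links",
            "subnetwork_links",
            "background_degree",
            "ratio",
            "rank",
        ],
    )


def subnetwork_to_list(sub: Subnetwork) -> GeneList:
    """Convert a subnetwork back into a gene list.

    Seeds first in input order (seeds missing from the background network
    are retained — list membership survives expansion), then intermediates
    in rank order.  The name gains an ``_expanded`` suffix.
    """
    genes = list(sub.seed_order) + [im.symbol for im in sub.ranked_intermediates()]
    return GeneList(name=f"{sub.name}_expanded", genes=tuple(genes))


def write_sif(sub: Subnetwork, path: str | Path, attrs_path: str | Path | None = None) -> Path:
    """Export a subnetwork as SIF plus a node-attribute sidecar table.

    One row per edge, ``nodeA<TAB>pp<TAB>nodeB``, endpoints in lexicographic
    order, rows sorted; isolated nodes as single-field rows.  The sidecar
    (default ``<path>.attrs.tsv``) lists every node with its role (seed or
    intermediate), specificity and rank.
    """
    path = Path(path)
    rows = []
    for u, v in sub.graph.edges:
        a, b = sorted((u, v))
        rows.append(f"{a}\tpp\t{b}")
    rows.sort()
    isolated = sorted(n for n in sub.graph.nodes if sub.graph.degree[n] == 0)
    path.write_text("".join(r + "\n" for r in rows + isolated), encoding="utf-8")

    attrs_path = Path(attrs_path) if attrs_path is not None else path.with_name(path.name + ".attrs.tsv")
    lines = ["node\trole\tspecificity\trank"]
    for s in sub.seeds:
        lines.append(f"{s}\tseed\t\t")
    for im in sub.ranked_intermediates():
        lines.append(f"{im.symbol}\tintermediate\t{im.specificity:.6g}\t{im.rank}")
    attrs_path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return path
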