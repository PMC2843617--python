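"""Seeded synthetic fixtures: universes, libraries with planted enrichment,
and background networks.

Every generator is a pure function of a :class:`FixtureSpec` — the same spec
always yields byte-identical output — so the whole package is testable
without downloading any real gene-set library or interaction database.

The default spec emulates a desk-scale enrichment screen: a universe of
2,000 gene symbols, a library of 50 sets of 50–150 genes each, and an
optional *planted* user list that shares an exact, known number of genes
with the library's first set (the planted term).  Background graphs come in
four flavours: preferential attachment (Barabási–Albert, a rough stand-in
for the heavy-tailed degree distribution of protein-interaction networks),
Erdős–Rényi, and exact chain / star topologies for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np

from .errors import DataError
from .genesets import GeneList, GeneSetLibrary, write_gene_list, write_gmt
from .networks import BackgroundNetwork, write_sif_network

__all__ = [
    "FixtureSpec",
    "make_universe",
    "make_library",
    "make_network",
    "write_fixture_files",
]

GRAPH_MODELS = ("preferential_attachment", "erdos_renyi", "chain", "star")


@dataclass
class FixtureSpec:
    """Deterministic recipe for one synthetic fixture family.

    ``planted`` is ``None`` or ``(user_list_size, overlap_fraction)``: the
    generated user list then shares exactly
    ``round(overlap_fraction * user_list_size)`` genes with the library's
    first set.  ``graph_params`` are model-specific (``n`` for chain/star,
    ``n, p`` for erdos_renyi, ``n, m`` for preferential_attachment).
    """

    seed: int = 0
    universe_size: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (50, 150)
    planted: tuple[int, float] | None = None
    graph_model: str = "preferential_attachment"
    graph_params: Mapping[str, Any] = field(default_factory=lambda: {"n": 100, "m": 2})

    def rng(self, salt: int) -> np.random.Generator:
        """One decoupled pseudo-random stream per generator."""
        return np.random.default_rng([self.seed, salt])


def make_universe(spec: FixtureSpec) -> tuple[str, ...]:
    """Deterministic gene symbols G000001, G000002, ..."""
    if spec.universe_size < 1:
        raise DataError("universe_size must be >= 1")
    return tuple(f"G{i:06d}" for i in range(1, spec.universe_size + 1))


def make_library(spec: FixtureSpec) -> tuple[GeneSetLibrary, GeneList | None]:
    """Sample a library of uniformly drawn gene sets, optionally with a
    planted enriched term.

    Each of the ``n_sets`` sets draws its size uniformly from
    ``set_size_range`` and its members uniformly without replacement from
    the universe.  With ``planted = (L, f)``, the FIRST set (``SET0001``) is
    the planted term: the returned user list of size L shares exactly
    ``round(f * L)`` genes with it, the remainder drawn from outside it.
    """
    lo, hi = spec.set_size_range
    if not 1 <= lo <= hi <= spec.universe_size:
        raise DataError(f"set_size_range {spec.set_size_range} infeasible for universe "
                        f"of {spec.universe_size}")
    universe = np.array(make_universe(spec))
    rng = spec.rng(1)
    sets = []
    for i in range(spec.n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        sets.append(GeneList(name=f"SET{i + 1:04d}", description="synthetic set",
                             genes=tuple(genes)))
    lib = GeneSetLibrary("synthetic_library", sets)

    user: GeneList | None = None
    if spec.planted is not None:
        if not sets:
            raise DataError("planted enrichment requires n_sets >= 1")
        user_size, frac = spec.planted
        if not 0.0 <= frac <= 1.0:
            raise DataError("overlap fraction must lie in [0, 1]")
        n_shared = round(frac * user_size)
        planted_set = sets[0]
        outside = np.array(sorted(set(universe) - set(planted_set.genes)))
        if n_shared > len(planted_set) or user_size - n_shared > len(outside):
            raise DataError(
                f"infeasible planted overlap: need {n_shared} of {len(planted_set)} "
                f"planted genes and {user_size - n_shared} of {len(outside)} outside genes"
            )
        rng_u = spec.rng(2)
        shared = rng_u.choice(np.array(planted_set.genes), size=n_shared, replace=False)
        rest = rng_u.choice(outside, size=user_size - n_shared, replace=False)
        user = GeneList(name="USER", description="synthetic planted user list",
                        genes=tuple(shared) + tuple(rest))
    return lib, user


def make_network(spec: FixtureSpec) -> BackgroundNetwork:
    """Build a background graph per the named model, nodes relabeled to
    universe-style gene symbols.

    ``chain`` and ``star`` are exact deterministic topologies; the random
    models derive their seed from the spec.
    """
    model = spec.graph_model
    params = dict(spec.graph_params)
    if model not in GRAPH_MODELS:
        raise DataError(f"unknown graph model {model!r}; expected one of {GRAPH_MODELS}")
    n = int(params.get("n", 0))
    if n < 1:
        raise DataError("graph parameter n must be >= 1")
    seed = int(spec.rng(3).integers(0, 2**31 - 1))
    if model == "chain":
        g = nx.path_graph(n)
    elif model == "star":
        g = nx.star_graph(n - 1)  # hub + (n-1) leaves
    elif model == "erdos_renyi":
        p = float(params.get("p", 0.1))
        if not 0.0 <= p <= 1.0:
            raise DataError("edge probability p must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        m = int(params.get("m", 2))
        if not 1 <= m < n:
            raise DataError("preferential attachment requires 1 <= m < n")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    mapping = {i: f"G{i + 1:06d}" for i in g.nodes}
    return BackgroundNetwork(nx.relabel_nodes(g, mapping), kind="custom")


def write_fixture_files(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit the fixture family as files in the dialects the readers accept.

    Writes ``library.gmt``, ``network.sif`` and, when a planted user list is
    requested, ``user_list.txt``.  Returns the paths by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lib, user = make_library(spec)
    net = make_network(spec)
    paths = {
        "library": write_gmt(lib, out_dir / "library.gmt"),
        "network": write_sif_network(net, out_dir / "network.sif"),
    }
    if user is not None:
        paths["user_list"] = write_gene_list(user, out_dir / "user_list.txt")
    return paths
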