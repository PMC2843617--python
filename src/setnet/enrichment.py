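"""Fisher-exact overlap statistics and multiple-testing correction.

The significance of the overlap between a user gene list (size ``a`` within
the universe) and a library gene set (size ``b``) is the one-sided
over-representation p-value under the hypergeometric null: with ``N`` the
background universe size and ``k`` the observed overlap,

    p = sum_{i=k}^{min(a,b)} C(b, i) * C(N-b, a-i) / C(N, a)

i.e. the probability of drawing at least ``k`` members of the library set
when sampling ``a`` genes from ``N`` without replacement.  This is the upper
tail of the Fisher exact test on the 2x2 overlap table, the standard test
for gene-set enrichment.  Tail sums are evaluated in log space (via
``scipy.stats.hypergeom``) so universes of tens of thousands of genes do not
overflow.

Per user list, raw p-values over a library's sets are adjusted by the
Bonferroni (family-wise) and Benjamini–Hochberg (false-discovery-rate)
procedures; both corrections are also available matrix-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .genesets import GeneList, GeneSetLibrary

__all__ = [
    "OverlapTest",
    "OverlapMatrix",
    "fisher_overlap",
    "bonferroni",
    "benjamini_hochberg",
    "overlap_matrix",
    "rank_terms",
    "write_enrichment_report",
    "write_matrix",
]

#: Universe policies for overlap_matrix.
UNIVERSE_POLICIES = ("library", "union", "custom")


@dataclass(frozen=True)
class OverlapTest:
    """One Fisher-exact overlap test between a user list and a library set.

    ``a`` and ``b`` are the list sizes after restriction to the universe;
    ``k`` is the overlap size and ``p_raw`` the hypergeometric upper-tail
    p-value.  ``degenerate`` marks tests where either list was empty after
    universe restriction (then ``k == 0`` and ``p_raw == 1``).
    """

    k: int
    a: int
    b: int
    N: int
    p_raw: float
    overlap_genes: tuple[str, ...]
    degenerate: bool = False


def fisher_overlap(
    user: GeneList,
    libset: GeneList,
    universe: frozenset[str] | set[str],
) -> OverlapTest:
    """Exact one-sided over-representation test of two gene lists.

    Both lists are restricted to universe membership before counting.
    Deterministic; an empty list after restriction yields the degenerate
    result ``k=0, p_raw=1``.
    """
    if not universe:
        raise DataError("empty background universe")
    N = len(universe)
    ua = [g for g in user.genes if g in universe]
    ub = frozenset(libset.genes) & frozenset(universe)
    a, b = len(ua), len(ub)
    overlap = tuple(g for g in ua if g in ub)
    k = len(overlap)
    if a == 0 or b == 0:
        return OverlapTest(k=0, a=a, b=b, N=N, p_raw=1.0, overlap_genes=(), degenerate=True)
    # P(X >= k) with X ~ Hypergeom(N, b, a); sf(k-1) is the upper tail at k.
    p = float(hypergeom.sf(k - 1, N, b, a))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return OverlapTest(k=k, a=a, b=b, N=N, p_raw=p, overlap_genes=overlap)


def _validate_pvalues(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise DataError("p-value input must be one-dimensional")
    if arr.size and (np.any(arr <= 0.0) or np.any(arr > 1.0) or np.any(~np.isfinite(arr))):
        raise DataError("p-values must lie in (0, 1]")
    return arr


def bonferroni(p: Sequence[float]) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, n*p) elementwise."""
    arr = _validate_pvalues(p)
    if arr.size == 0:
        return arr
    return np.minimum(arr * arr.size, 1.0)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR-adjusted p-values, in input order.

    Sort ascending, set q_i = p_i * n / i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    arr = _validate_pvalues(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class OverlapMatrix:
    """All pairwise overlap tests between user lists and a library.

    Rows are library set labels, columns user list labels.  ``cells`` maps
    ``(set_label, user_label)`` to the :class:`OverlapTest`; the three
    DataFrames hold raw and corrected p-values on the same axes.  Every cell
    shares one universe ``N``.  Corrections are computed per user-list
    column over the library's sets (or matrix-wide when requested).
    """

    universe: frozenset[str]
    cells: dict[tuple[str, str], OverlapTest]
    p_raw: pd.DataFrame
    p_bonferroni: pd.DataFrame
    p_bh: pd.DataFrame
    users: dict[str, GeneList]
    library: GeneSetLibrary
    dropped_user_genes: dict[str, int]

    @property
    def user_labels(self) -> list[str]:
        return list(self.p_raw.columns)

    @property
    def set_labels(self) -> list[str]:
        return list(self.p_raw.index)


def resolve_universe(
    users: Sequence[GeneList],
    library: GeneSetLibrary,
    policy: str = "library",
    universe: Iterable[str] | None = None,
) -> frozenset[str]:
    """Resolve the background universe N under the chosen policy.

    ``library``: the union of the library's member genes (default).
    ``union``: library universe plus every user-list gene.
    ``custom``: an explicitly supplied gene collection.
    """
    if policy not in UNIVERSE_POLICIES:
        raise DataError(f"unknown universe policy {policy!r}; expected one of {UNIVERSE_POLICIES}")
    if policy == "custom":
        if universe is None:
            raise DataError("universe policy 'custom' requires an explicit universe")
        resolved = frozenset(universe)
    elif policy == "union":
        u = set(library.universe)
        for gl in users:
            u.update(gl.genes)
        resolved = frozenset(u)
    else:
        resolved = library.universe
    if not resolved:
        raise DataError("background universe is empty under the chosen policy")
    return resolved


def overlap_matrix(
    users: Sequence[GeneList],
    library: GeneSetLibrary,
    universe_policy: str = "library",
    universe: Iterable[str] | None = None,
    correction_scope: str = "column",
) -> OverlapMatrix:
    """Compute the overlap matrix between user lists and a library.

    One :class:`OverlapTest` per (library set, user list) pair, all sharing
    the same universe.  ``correction_scope`` is ``"column"`` (default:
    corrected p-value vectors computed per user-list column over the
    library's sets) or ``"matrix"`` (one correction family over all cells).
    """
    users = list(users)
    if not users:
        raise DataError("at least one user list is required")
    if len(library) == 0:
        raise DataError("library is empty")
    labels = [gl.name for gl in users]
    if len(set(labels)) != len(labels):
        raise DataError("user list names must be unique")
    if correction_scope not in ("column", "matrix"):
        raise DataError(f"unknown correction scope {correction_scope!r}")

    uni = resolve_universe(users, library, universe_policy, universe)
    cells: dict[tuple[str, str], OverlapTest] = {}
    dropped = {}
    for ul in users:
        dropped[ul.name] = sum(1 for g in ul.genes if g not in uni)
        for ls in library:
            cells[(ls.name, ul.name)] = fisher_overlap(ul, ls, uni)

    set_labels = library.names
    raw = pd.DataFrame(
        {ul.name: [cells[(s, ul.name)].p_raw for s in set_labels] for ul in users},
        index=set_labels,
    )
    if correction_scope == "column":
        bonf = raw.apply(lambda col: bonferroni(col.to_numpy()), axis=0)
        bh = raw.apply(lambda col: benjamini_hochberg(col.to_numpy()), axis=0)
    else:
        flat = raw.to_numpy().ravel()
        bonf = pd.DataFrame(
            bonferroni(flat).reshape(raw.shape), index=raw.index, columns=raw.columns
        )
        bh = pd.DataFrame(
            benjamini_hochberg(flat).reshape(raw.shape), index=raw.index, columns=raw.columns
        )
    return OverlapMatrix(
        universe=uni,
        cells=cells,
        p_raw=raw,
        p_bonferroni=bonf,
        p_bh=bh,
        users={gl.name: gl for gl in users},
        library=library,
        dropped_user_genes=dropped,
    )


def rank_terms(matrix: OverlapMatrix, column: str) -> pd.DataFrame:
    """Ranked enrichment table for one user-list column.

    Rows sorted by ascending raw p-value; ties broken by descending overlap
    size, then term label.  Columns: term, k, a, b, N, p_raw, p_bonferroni,
    p_bh, overlap_genes.
    """
    if column not in matrix.p_raw.columns:
        raise DataError(f"unknown user-list column {column!r}")
    records = []
    for s in matrix.set_labels:
        t = matrix.cells[(s, column)]
        records.append(
            {
                "term": s,
                "k": t.k,
                "a": t.a,
                "b": t.b,
                "N": t.N,
                "p_raw": t.p_raw,
                "p_bonferroni": float(matrix.p_bonferroni.loc[s, column]),
                "p_bh": float(matrix.p_bh.loc[s, column]),
                "overlap_genes": ";".join(t.overlap_genes),
            }
        )
    table = pd.DataFrame.from_records(
        records,
        columns=["term", "k", "a", "b", "N", "p_raw", "p_bonferroni", "p_bh", "overlap_genes"],
    )
    if len(table):
        table = (
            table.assign(_negk=-table["k"])
            .sort_values(["p_raw", "_negk", "term"], kind="mergesort")
            .drop(columns="_negk")
            .reset_index(drop=True)
        )
    return table


def write_enrichment_report(table: pd.DataFrame, path: str | Path) -> Path:
    """Write one user list's ranked enrichment table as TSV."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def write_matrix(matrix: OverlapMatrix, path: str | Path) -> Path:
    """Write the combined raw p-value matrix (terms x lists) as TSV."""
    path = Path(path)
    matrix.p_raw.to_csv(path, sep="\t", index_label="term")
    return path
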