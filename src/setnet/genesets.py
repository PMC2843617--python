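"""Gene-symbol normalization, gene lists, GMT libraries, and set algebra.

The central containers are :class:`GeneList` (a named, ordered, duplicate-free
collection of normalized gene symbols) and :class:`GeneSetLibrary` (an ordered
collection of gene lists read from one GMT file, with a cached background
universe).  Symbols are canonicalized to upper case, the convention for human
Entrez gene symbols; an optional :class:`SynonymTable` maps aliases onto
canonical symbols at normalization time.

File formats handled here:

* GMT (Gene Matrix Transposed): tab-delimited, one gene set per row — set
  name, description, then member symbols.
* Plain gene-list text: one symbol per line, ``#`` comment lines ignored.
* Synonym table: two tab-delimited columns, alias then canonical symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import DataError

__all__ = [
    "SynonymTable",
    "GeneList",
    "GeneSetLibrary",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_synonym_table",
    "set_union",
    "set_intersection",
    "set_subtract",
]


class SynonymTable:
    """Maps alias symbols to canonical symbols.

    Aliases map directly to canonicals (no chains): if an entry's canonical
    symbol is itself an alias of a third symbol the table is rejected.
    Canonical symbols may map to themselves.
    """

    def __init__(self, mapping: Mapping[str, str]):
        norm: dict[str, str] = {}
        for alias, canonical in mapping.items():
            a = _basic_normalize(alias)
            c = _basic_normalize(canonical)
            norm[a] = c
        for alias, canonical in norm.items():
            target = norm.get(canonical)
            if target is not None and target != canonical:
                raise DataError(
                    f"synonym chain: {alias!r} -> {canonical!r} -> {target!r};"
                    " aliases must map directly to canonical symbols"
                )
        self._mapping = norm

    def resolve(self, symbol: str) -> str:
        return self._mapping.get(symbol, symbol)

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._mapping


def _basic_normalize(raw: str, context: str = "") -> str:
    s = raw.strip()
    if not s:
        where = f" ({context})" if context else ""
        raise DataError(f"empty gene symbol{where}")
    if "\t" in s or "\n" in s or "\r" in s:
        raise DataError(f"gene symbol contains tab/newline: {raw!r}")
    return s.upper()


def normalize_symbol(raw: str, synonyms: SynonymTable | None = None, context: str = "") -> str:
    """Return the canonical form of a raw gene symbol.

    Strips surrounding whitespace, upper-cases, then applies the synonym
    table if one is supplied.  Idempotent: normalizing an already-normalized
    symbol is a no-op.  Empty-after-strip input raises :class:`DataError`
    mentioning ``context`` (e.g. the offending file line).
    """
    s = _basic_normalize(raw, context)
    if synonyms is not None:
        s = synonyms.resolve(s)
    return s


@dataclass
class GeneList:
    """A named, described, ordered collection of unique normalized symbols."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()
    duplicates_dropped: int = field(default=0, compare=False)

    @classmethod
    def build(
        cls,
        name: str,
        symbols: Iterable[str],
        description: str = "",
        synonyms: SynonymTable | None = None,
        context: str = "",
    ) -> "GeneList":
        """Normalize, deduplicate (first occurrence kept) and wrap symbols."""
        seen: dict[str, None] = {}
        dropped = 0
        for raw in symbols:
            if raw is None or not raw.strip():
                continue  # empty cells are silently dropped
            sym = normalize_symbol(raw, synonyms, context)
            if sym in seen:
                dropped += 1
            else:
                seen[sym] = None
        return cls(name=name, description=description, genes=tuple(seen), duplicates_dropped=dropped)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def is_empty(self) -> bool:
        return not self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


class GeneSetLibrary:
    """An ordered collection of labeled gene lists (one GMT file).

    Set names must be unique within a library.  The ``universe`` — the union
    of all member symbols — is derived on first access and cached; it is the
    default background population for enrichment tests.
    """

    def __init__(self, name: str, sets: Iterable[GeneList]):
        self.name = name
        self.sets: list[GeneList] = list(sets)
        seen: set[str] = set()
        for gl in self.sets:
            if gl.name in seen:
                raise DataError(f"duplicate set name in library: {gl.name!r}")
            seen.add(gl.name)
        self._by_name = {gl.name: gl for gl in self.sets}
        self._universe: frozenset[str] | None = None

    @property
    def universe(self) -> frozenset[str]:
        if self._universe is None:
            u: set[str] = set()
            for gl in self.sets:
                u.update(gl.genes)
            self._universe = frozenset(u)
        return self._universe

    @property
    def names(self) -> list[str]:
        return [gl.name for gl in self.sets]

    @property
    def duplicates_dropped(self) -> int:
        return sum(gl.duplicates_dropped for gl in self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneList]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key: int | str) -> GeneList:
        if isinstance(key, int):
            return self.sets[key]
        try:
            return self._by_name[key]
        except KeyError:
            raise KeyError(f"no gene set named {key!r} in library {self.name!r}") from None


def read_gmt(
    path: str | Path,
    synonyms: SynonymTable | None = None,
    name: str | None = None,
) -> GeneSetLibrary:
    """Read a GMT file into a :class:`GeneSetLibrary`.

    Column 1 is the set name, column 2 the description, columns 3.. the
    member symbols (normalized, deduplicated, empty cells dropped).  Row
    order is preserved.  Unix and Windows line endings are both accepted.
    """
    path = Path(path)
    sets: list[GeneList] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path.name}: row {lineno}: fewer than 2 columns")
            set_name = fields[0].strip()
            if not set_name:
                raise DataError(f"{path.name}: row {lineno}: empty set name")
            gl = GeneList.build(
                set_name,
                fields[2:],
                description=fields[1],
                synonyms=synonyms,
                context=f"{path.name} row {lineno}",
            )
            sets.append(gl)
    return GeneSetLibrary(name or path.stem, sets)


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> Path:
    """Write a library as a GMT file (Unix line endings).

    ``read_gmt(write_gmt(lib))`` reproduces names, descriptions and gene
    collections exactly.  Set names or descriptions containing a tab are
    rejected, since they would corrupt the column structure.
    """
    path = Path(path)
    rows = []
    for gl in lib.sets:
        for label, what in ((gl.name, "set name"), (gl.description, "description")):
            if "\t" in label or "\n" in label or "\r" in label:
                raise DataError(f"{what} contains tab/newline: {label!r}")
        rows.append("\t".join([gl.name, gl.description, *gl.genes]))
    path.write_text("".join(r + "\n" for r in rows), encoding="utf-8")
    return path


def read_gene_list(
    path: str | Path,
    name: str | None = None,
    synonyms: SynonymTable | None = None,
) -> GeneList:
    """Read a plain gene-list text file: one symbol per line, ``#`` comments ignored."""
    path = Path(path)
    symbols: list[str] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            symbols.append(s)
    return GeneList.build(name or path.stem, symbols, synonyms=synonyms, context=path.name)


def write_gene_list(gl: GeneList, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(g + "\n" for g in gl.genes), encoding="utf-8")
    return path


def read_synonym_table(path: str | Path) -> SynonymTable:
    """Read a two-column tab-delimited alias → canonical mapping."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path.name}: row {lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return SynonymTable(mapping)


def set_union(a: GeneList, b: GeneList) -> GeneList:
    """Union: operand-a order first, then operand-b novelties."""
    genes = a.genes + tuple(g for g in b.genes if g not in a.symbols)
    return GeneList(name=f"{a.name}+{b.name}", genes=genes)


def set_intersection(a: GeneList, b: GeneList) -> GeneList:
    """Intersection, in operand-a order."""
    genes = tuple(g for g in a.genes if g in b.symbols)
    return GeneList(name=f"{a.name}&{b.name}", genes=genes)


def set_subtract(a: GeneList, b: GeneList) -> GeneList:
    """Set difference a \\ b (the "not" operation), in operand-a order."""
    genes = tuple(g for g in a.genes if g not in b.symbols)
    return GeneList(name=f"{a.name}-{b.name}", genes=genes)
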