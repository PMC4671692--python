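"""Gene symbol lists: loading, normalisation, deduplication and the gene universe.

Every statistic downstream is computed over sets of gene *symbols*.  Lists
merged from many sources are only comparable after a common normalisation:
symbols are whitespace-trimmed and uppercased, optional alias→official
mappings are applied, and duplicates and blanks are removed (with counts,
never silently).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ContractError

logger = logging.getLogger(__name__)

#: Number of genes in the GENCODE v22 annotation of the human genome, the
#: default universe size for all overlap statistics.
DEFAULT_UNIVERSE_SIZE = 19_814


@dataclass(frozen=True)
class NormalizationReport:
    """Per-file accounting of what normalisation did to the raw records."""

    n_raw: int
    n_kept: int
    n_blank: int
    n_duplicate: int
    n_aliased: int

    def __post_init__(self) -> None:
        if self.n_kept > self.n_raw:
            raise ContractError("kept more records than were read")


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of normalised gene symbols.

    ``n_raw`` is the number of input records before normalisation, so
    ``len(gs) <= gs.n_raw`` always holds.
    """

    name: str
    members: frozenset[str]
    provenance: str = ""
    n_raw: int | None = None
    report: NormalizationReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if any(not m for m in self.members):
            raise ContractError(f"gene set {self.name!r} contains an empty symbol")
        if self.n_raw is None:
            object.__setattr__(self, "n_raw", len(self.members))
        if len(self.members) > self.n_raw:
            raise ContractError(
                f"gene set {self.name!r}: |members|={len(self.members)} exceeds n_raw={self.n_raw}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass(frozen=True)
class GeneUniverse:
    """The pool of N genes all overlap statistics condition on.

    ``members`` is optional: the default mode mirrors published overlap
    arithmetic, which uses raw list sizes against a fixed N without an
    explicit symbol catalogue.
    """

    size: int = DEFAULT_UNIVERSE_SIZE
    members: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ContractError(f"universe size must be >= 1, got {self.size}")
        if self.members is not None:
            object.__setattr__(self, "members", frozenset(self.members))
            if len(self.members) != self.size:
                raise ContractError(
                    f"universe declares size {self.size} but has {len(self.members)} members"
                )


class SymbolMap:
    """Alias → official symbol mapping (a function: one official per alias)."""

    def __init__(self, pairs: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        self._map: dict[str, str] = {}
        for alias, official in items:
            a, o = alias.strip().upper(), official.strip().upper()
            if not a or not o:
                raise ContractError("symbol map contains a blank alias or official symbol")
            if a in self._map and self._map[a] != o:
                raise ContractError(f"alias {a!r} maps to both {self._map[a]!r} and {o!r}")
            self._map[a] = o

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, alias: str) -> bool:
        return alias in self._map

    def resolve(self, symbol: str) -> str:
        """Return the official symbol for ``symbol`` (identity if not an alias)."""
        return self._map.get(symbol, symbol)


def load_symbol_map(path: str | Path) -> SymbolMap:
    """Read an alias→official two-column TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ContractError(f"symbol map {path} must have two columns (alias, official)")
    return SymbolMap(zip(df.iloc[:, 0].fillna(""), df.iloc[:, 1].fillna("")))


def normalize_symbols(
    records: Iterable[str], symbol_map: SymbolMap | None = None
) -> tuple[list[str], NormalizationReport]:
    """Trim, uppercase, alias-map and deduplicate raw symbol records.

    Returns the kept symbols in first-occurrence order plus a count report.
    Blank records are dropped and counted; duplicates keep the first
    occurrence.
    """
    kept: list[str] = []
    seen: set[str] = set()
    n_raw = n_blank = n_dup = n_aliased = 0
    for rec in records:
        n_raw += 1
        sym = str(rec).strip().upper()
        if not sym or sym == "NAN":
            n_blank += 1
            continue
        if symbol_map is not None:
            mapped = symbol_map.resolve(sym)
            if mapped != sym:
                n_aliased += 1
            sym = mapped
        if sym in seen:
            n_dup += 1
            continue
        seen.add(sym)
        kept.append(sym)
    report = NormalizationReport(
        n_raw=n_raw, n_kept=len(kept), n_blank=n_blank, n_duplicate=n_dup, n_aliased=n_aliased
    )
    return kept, report


def load_gene_list(
    path: str | Path,
    name: str | None = None,
    symbol_map: SymbolMap | None = None,
    symbol_col: str | None = None,
) -> GeneSet:
    """Read a gene list from disk into a normalised :class:`GeneSet`.

    Parameters
    ----------
    path
        UTF-8 text file, one symbol per line; or, when ``symbol_col`` is
        given, a TSV with a header row containing that column.
    name
        Label for the set; defaults to the file stem.
    symbol_map
        Optional alias→official mapping applied after uppercasing.
    symbol_col
        Column holding the symbols when the input is a table.
    """
    path = Path(path)
    if symbol_col is not None:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if symbol_col not in df.columns:
            raise ContractError(f"{path}: no column named {symbol_col!r}")
        records = df[symbol_col].fillna("").tolist()
    else:
        records = path.read_text(encoding="utf-8").splitlines()
    members, report = normalize_symbols(records, symbol_map)
    logger.info(
        "loaded %s: n_raw=%d n_kept=%d n_blank=%d n_duplicate=%d n_aliased=%d",
        path, report.n_raw, report.n_kept, report.n_blank, report.n_duplicate, report.n_aliased,
    )
    if not members:
        logger.warning("gene list %s normalised to an empty set", path)
    return GeneSet(
        name=name or path.stem,
        members=frozenset(members),
        provenance=str(path),
        n_raw=report.n_raw,
        report=report,
    )


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    """Write one symbol per line, sorted (loading it back is a fixed point)."""
    Path(path).write_text("\n".join(sorted(gs.members)) + "\n", encoding="utf-8")


def restrict_to_universe(s: GeneSet, u: GeneUniverse) -> GeneSet:
    """Intersect a gene set with an explicit universe (strict mode).

    The default analysis mode does *not* apply this: published overlap
    arithmetic uses raw list sizes against a fixed N.
    """
    if u.members is None:
        raise ContractError("restrict_to_universe requires a universe with explicit members")
    kept = s.members & u.members
    n_dropped = len(s.members) - len(kept)
    if n_dropped:
        logger.info("restricted %s to universe: dropped %d symbols", s.name, n_dropped)
    return GeneSet(name=s.name, members=kept, provenance=s.provenance, n_raw=s.n_raw)
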