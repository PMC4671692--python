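"""Assign non-coding genomic intervals to genes by regulatory domains.

Each gene receives a strand-aware *basal* window around its TSS (default
5 kb upstream, 1 kb downstream), then an *extension* outward from the basal
edges up to ``max_ext`` (default 1 Mb) or to the neighbouring gene's basal
window, whichever is nearer — the classic basal-plus-extension association
rule.  An interval is assigned to every gene whose domain it intersects by
at least one base.  All coordinates are 0-based half-open (BED convention);
the TSS of a minus-strand gene is the higher genomic coordinate of its
model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ContractError
from .genesets import GeneSet

logger = logging.getLogger(__name__)

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ContractError(f"bad interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ContractError(f"{self.symbol}: TSS must be >= 0")
        if self.strand not in ("+", "-"):
            raise ContractError(f"{self.symbol}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class RegulatoryDomain:
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ContractError(f"empty domain for {self.symbol}")


def basal_window(g: GeneModel, basal_up: int = BASAL_UPSTREAM,
                 basal_down: int = BASAL_DOWNSTREAM) -> tuple[int, int]:
    """Strand-aware (start, end) of the basal window, clipped at 0."""
    if g.strand == "+":
        lo, hi = g.tss - basal_up, g.tss + basal_down
    else:
        lo, hi = g.tss - basal_down, g.tss + basal_up
    return max(0, lo), max(0, hi)


def basal_extension_domains(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    basal_up: int = BASAL_UPSTREAM,
    basal_down: int = BASAL_DOWNSTREAM,
    max_ext: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Materialise the basal-plus-extension regulatory domain of every gene.

    Extension runs from each basal edge outward by at most ``max_ext`` bp
    and stops at a neighbouring gene's basal window; domains never shrink
    below the gene's own basal window and are clipped to [0, chrom length).
    """
    unknown = [g.symbol for g in genes if g.chrom not in chrom_sizes]
    if unknown:
        raise ContractError(f"genes on unknown chromosomes: {', '.join(sorted(unknown))}")
    out: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        size = chrom_sizes[chrom]
        glist = sorted(glist, key=lambda g: (g.tss, g.symbol))
        basals = [basal_window(g, basal_up, basal_down) for g in glist]
        n = len(glist)
        # prefix max of basal ends before i / suffix min of basal starts after i
        prefix = [0] * n
        running = 0
        for i in range(n):
            prefix[i] = running
            running = max(running, basals[i][1])
        suffix = [size] * n
        running = size
        for i in range(n - 1, -1, -1):
            suffix[i] = running
            running = min(running, basals[i][0])
        for g, (b_lo, b_hi), left_stop, right_stop in zip(glist, basals, prefix, suffix):
            start = max(0, min(b_lo, max(b_lo - max_ext, left_stop)))
            end = min(size, max(b_hi, min(b_hi + max_ext, right_stop)))
            out.append(RegulatoryDomain(symbol=g.symbol, chrom=chrom, start=start, end=end))
    return out


def assign_regions(
    intervals: Sequence[GenomicInterval],
    domains: Sequence[RegulatoryDomain],
) -> list[frozenset[str]]:
    """Map each interval to the genes whose domains it overlaps (>= 1 bp).

    Returns one gene-symbol set per input interval, in input order.
    Intervals on chromosomes absent from the domain list are logged and
    assigned to nothing.
    """
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end, d.symbol)
    out: list[frozenset[str]] = []
    for iv in intervals:
        tree = trees.get(iv.chrom)
        if tree is None:
            logger.warning("interval %s:%d-%d on chromosome absent from domains",
                           iv.chrom, iv.start, iv.end)
            out.append(frozenset())
            continue
        out.append(frozenset(hit.data for hit in tree.overlap(iv.start, iv.end)))
    return out


def assigned_gene_set(assignments: Sequence[frozenset[str]], name: str) -> GeneSet:
    """Deduplicated union of all assigned genes, consumable by the overlap layer."""
    members = frozenset().union(*assignments) if assignments else frozenset()
    return GeneSet(name=name, members=members, provenance="region-to-gene assignment")


# ---------------------------------------------------------------------------
# I/O

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED4 intervals (track/browser/comment lines skipped)."""
    out: list[GenomicInterval] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(GenomicInterval(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                   id=f[3] if len(f) > 3 else None))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    lines = []
    for iv in intervals:
        f = [iv.chrom, str(iv.start), str(iv.end)] + ([iv.id] if iv.id else [])
        lines.append("\t".join(f))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """TSV with columns symbol, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "tss": int, "strand": str})
    required = {"symbol", "chrom", "tss", "strand"}
    if not required <= set(df.columns):
        raise ContractError(f"{path}: gene-model TSV needs columns {sorted(required)}")
    return [GeneModel(symbol=r.symbol, chrom=r.chrom, tss=int(r.tss), strand=r.strand)
            for r in df.itertuples()]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [{"symbol": g.symbol, "chrom": g.chrom, "tss": g.tss, "strand": g.strand} for g in genes]
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp (no header)."""
    out: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            name, size = line.split("\t")[:2]
            out[name] = int(size)
    return out


def assignments_to_frame(
    intervals: Sequence[GenomicInterval], assignments: Sequence[frozenset[str]]
) -> pd.DataFrame:
    rows = []
    for iv, genes in zip(intervals, assignments):
        rows.append({
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "id": iv.id or "", "genes": ";".join(sorted(genes)),
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "genes"])
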