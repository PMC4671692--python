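"""Gene-set overlap statistics: representation factor, hypergeometric test,
Venn partitions and union summaries.

The representation factor (RF) of two lists of sizes ``n_a`` and ``n_b``
sharing ``k`` genes out of a universe of ``N`` is

    RF = k / (n_a * n_b / N),

the observed overlap divided by the overlap expected for two independent
draws.  RF > 1 means more overlap than chance.  Significance is the exact
hypergeometric upper tail P(X >= k) for X ~ Hypergeometric(N, n_a, n_b),
inclusive, so k = 0 gives p = 1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ContractError, UndefinedRFError
from .genesets import GeneSet, GeneUniverse


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (2.25 -> 2.3, -2.25 -> -2.3).

    Python's builtin ``round`` is banker's rounding; published one-decimal
    values follow the conventional half-away rule instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def representation_factor(n_a: int, n_b: int, k: int, N: int) -> float:
    """Observed overlap divided by the expected overlap of independent draws.

    Raises :class:`UndefinedRFError` when either list is empty, and
    :class:`ContractError` on impossible counts.  k = 0 gives RF = 0.
    """
    if n_a < 1 or n_b < 1:
        raise UndefinedRFError(f"RF undefined for empty list (n_a={n_a}, n_b={n_b})")
    if N < max(n_a, n_b):
        raise ContractError(f"universe N={N} smaller than a list ({n_a}, {n_b})")
    if not 0 <= k <= min(n_a, n_b):
        raise ContractError(f"overlap k={k} outside [0, min({n_a}, {n_b})]")
    return k / (n_a * n_b / N)


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    This is the tail the standard online overlap calculators report: the
    probability of at least ``k`` shared genes between a K-gene and an
    n-gene list drawn without replacement from N genes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ContractError(f"counts K={K}, n={n} incompatible with N={N}")
    if not 0 <= k <= min(K, n):
        raise ContractError(f"k={k} outside [0, min({K}, {n})]")
    # sf(k-1) = P(X > k-1) = P(X >= k); clamp out tiny negative fp noise
    return float(min(1.0, max(0.0, hypergeom.sf(k - 1, N, K, n))))


@dataclass(frozen=True)
class OverlapResult:
    """The statistic bundle for one pairwise overlap."""

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    k: int
    N: int
    expected: float
    rf: float
    p_upper: float

    @property
    def rf_reported(self) -> float:
        """RF rounded to one decimal, half away from zero (display convention)."""
        return round_half_away(self.rf, 1)

    def to_dict(self) -> dict:
        d = {
            "name_a": self.name_a, "name_b": self.name_b,
            "n_a": self.n_a, "n_b": self.n_b, "k": self.k, "N": self.N,
            "expected": self.expected, "rf": self.rf,
            "rf_reported": self.rf_reported, "p_upper": self.p_upper,
        }
        return d


@dataclass(frozen=True)
class UnionOverlapResult(OverlapResult):
    """Overlap of a target list with the union of several lists, plus the
    percentage of the target covered (the "total unique" summary column)."""

    part_names: tuple[str, ...] = ()

    @property
    def percent_of_target(self) -> float:
        return round_half_away(100.0 * self.k / self.n_a, 1)

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["percent_of_target"] = self.percent_of_target
        d["part_names"] = list(self.part_names)
        return d


def overlap_counts(
    n_a: int, n_b: int, k: int, N: int, name_a: str = "A", name_b: str = "B"
) -> OverlapResult:
    """Count-mode overlap: the full statistic bundle from sizes alone.

    This is how published overlap tables are reproduced when the underlying
    membership lists are unavailable.
    """
    rf = representation_factor(n_a, n_b, k, N)
    expected = n_a * n_b / N
    p = hypergeom_upper(N, n_a, n_b, k)
    return OverlapResult(
        name_a=name_a, name_b=name_b, n_a=n_a, n_b=n_b, k=k, N=N,
        expected=expected, rf=rf, p_upper=p,
    )


def overlap(a: GeneSet, b: GeneSet, u: GeneUniverse) -> OverlapResult:
    """Membership-mode overlap of two gene sets over universe ``u``."""
    if len(a) == 0 or len(b) == 0:
        raise UndefinedRFError(f"overlap undefined for empty set ({a.name!r} or {b.name!r})")
    k = len(a.members & b.members)
    return overlap_counts(len(a), len(b), k, u.size, name_a=a.name, name_b=b.name)


def union_overlap(
    target: GeneSet, parts: Sequence[GeneSet], u: GeneUniverse
) -> UnionOverlapResult:
    """Overlap of ``target`` with the union of ``parts`` ("total unique" column)."""
    if not parts:
        raise ContractError("union_overlap needs at least one part")
    union_members = frozenset().union(*(p.members for p in parts))
    union_name = "|".join(p.name for p in parts)
    if len(target) == 0 or not union_members:
        raise UndefinedRFError("union_overlap undefined for an empty set")
    k = len(target.members & union_members)
    n_u = len(union_members)
    return UnionOverlapResult(
        name_a=target.name, name_b=f"union({union_name})",
        n_a=len(target), n_b=n_u, k=k, N=u.size,
        expected=len(target) * n_u / u.size,
        rf=representation_factor(len(target), n_u, k, u.size),
        p_upper=hypergeom_upper(u.size, len(target), n_u, k),
        part_names=tuple(p.name for p in parts),
    )


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region membership for 2-4 sets.

    ``regions`` maps each non-empty subset signature (a frozenset of set
    names) to the genes belonging to exactly those sets; there are
    ``2**m - 1`` regions, pairwise disjoint, covering the union.
    """

    set_names: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]] = field(compare=False)

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {sig: len(genes) for sig, genes in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sig in sorted(self.regions, key=lambda s: (len(s), sorted(s))):
            rows.append({
                "signature": "&".join(sorted(sig)),
                "count": len(self.regions[sig]),
                "genes": ";".join(sorted(self.regions[sig])),
            })
        return pd.DataFrame(rows, columns=["signature", "count", "genes"])


def venn_partition(sets: Sequence[GeneSet]) -> VennPartition:
    """Partition the union of 2-4 gene sets into exclusive Venn regions."""
    m = len(sets)
    if not 2 <= m <= 4:
        raise ContractError(f"venn_partition supports 2-4 sets, got {m}")
    names = tuple(s.name for s in sets)
    if len(set(names)) != m:
        raise ContractError("set names must be distinct")
    by_name = {s.name: s.members for s in sets}
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, m + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = set()
    for gene in frozenset().union(*by_name.values()):
        sig = frozenset(n for n in names if gene in by_name[n])
        regions[sig].add(gene)
    return VennPartition(
        set_names=names,
        regions={sig: frozenset(g) for sig, g in regions.items()},
    )


def permutation_null(
    n_a: int, n_b: int, N: int, reps: int, seed: int
) -> np.ndarray:
    """Empirical null of the overlap count for random list pairs.

    Draws ``reps`` independent pairs of uniform random subsets of sizes
    ``n_a`` and ``n_b`` from an ``N``-gene universe and returns the realised
    intersection sizes (marginally Hypergeometric(N, n_a, n_b)).  Cross-check
    for the analytic tail, fully reproducible under ``seed``.
    """
    if reps < 1:
        raise ContractError("reps must be >= 1")
    if max(n_a, n_b) > N:
        raise ContractError("list sizes exceed universe")
    rng = np.random.default_rng(seed)
    ks = np.empty(reps, dtype=np.int64)
    mask = np.zeros(N, dtype=bool)
    for i in range(reps):
        a = rng.choice(N, size=n_a, replace=False)
        b = rng.choice(N, size=n_b, replace=False)
        mask[a] = True
        ks[i] = int(mask[b].sum())
        mask[a] = False
    return ks


def empirical_upper_tail(ks: np.ndarray, k_obs: int) -> float:
    """P(k >= k_obs) under the empirical null returned by :func:`permutation_null`."""
    return float(np.mean(ks >= k_obs))


def results_to_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Tidy table, one overlap per row."""
    return pd.DataFrame([r.to_dict() for r in results])


def write_results(results: Sequence[OverlapResult], tsv: str | Path, json_path: str | Path | None = None) -> None:
    """Write the tidy TSV and (optionally) its full-precision JSON mirror."""
    df = results_to_frame(results)
    df.to_csv(tsv, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps([r.to_dict() for r in results], indent=1))
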