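"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and an integer seed:
outputs are byte-identical across runs.  Deterministic planting modes place
exact overlap counts / enrichment calls so tests can assert sharp recovery;
stochastic modes sample independently so the analytic null distributions can
be validated.  Synthetic symbols are zero-padded ("G000001") so that
lexicographic and numeric orders coincide.
"""
from __future__ import annotations

import json
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InfeasibleSpecError
from .genesets import GeneSet, GeneUniverse
from .regions import (GeneModel, GenomicInterval,
                      basal_extension_domains, write_bed, write_gene_models)
from .enrichment import AnnotationTable

#: Log-scale parameters of the background expression distribution
#: (right-skewed, like bulk expression data).
LOGNORMAL_MEAN = 1.0
LOGNORMAL_SIGMA = 1.0


def gen_universe(N: int, seed: int = 0) -> GeneUniverse:
    """A universe of ``N`` synthetic symbols G000001..G<N>, zero-padded."""
    if N < 1:
        raise ContractError(f"universe size must be >= 1, got {N}")
    width = max(6, len(str(N)))
    members = frozenset(f"G{i:0{width}d}" for i in range(1, N + 1))
    return GeneUniverse(size=N, members=members)


def _ordered(u: GeneUniverse) -> list[str]:
    assert u.members is not None
    return sorted(u.members)


def gen_overlapping_sets(
    u: GeneUniverse,
    sizes: Mapping[str, int],
    overlaps: Mapping[tuple[str, str], int] | None = None,
    triple: int | None = None,
    mode: str = "deterministic",
    seed: int = 0,
) -> tuple[dict[str, GeneSet], dict]:
    """Named gene sets with planted or naturally arising intersections.

    Deterministic mode (2 or 3 sets) allocates disjoint universe blocks per
    Venn region so every pairwise overlap (and the triple intersection,
    default 0) is realised *exactly*.  Stochastic mode samples each set
    independently and uniformly at its stated size, so pairwise overlaps are
    Hypergeometric(N, n_a, n_b).

    Returns the sets plus a truth table: realised k for every pair and, in
    deterministic mode, the planted region sizes.
    """
    names = list(sizes)
    if any(sizes[n] < 1 for n in names):
        raise ContractError("set sizes must be >= 1")
    if any(sizes[n] > u.size for n in names):
        raise InfeasibleSpecError("a set size exceeds the universe")
    rng = np.random.default_rng(seed)
    pool = _ordered(u)

    if mode == "stochastic":
        sets = {}
        for n in names:
            idx = rng.choice(u.size, size=sizes[n], replace=False)
            sets[n] = GeneSet(name=n, members=frozenset(pool[i] for i in idx),
                              provenance="synthetic (stochastic)")
        truth = {
            "mode": "stochastic",
            "pairs": {f"{a}|{b}": len(sets[a].members & sets[b].members)
                      for a, b in combinations(names, 2)},
        }
        return sets, truth

    if mode != "deterministic":
        raise ContractError(f"unknown mode {mode!r}")
    if len(names) not in (2, 3):
        raise InfeasibleSpecError("deterministic planting supports 2 or 3 sets")
    overlaps = dict(overlaps or {})

    def k_of(a: str, b: str) -> int:
        return overlaps.get((a, b), overlaps.get((b, a), 0))

    # Venn region sizes by inclusion-exclusion
    region_size: dict[frozenset[str], int] = {}
    if len(names) == 2:
        a, b = names
        kab = k_of(a, b)
        region_size[frozenset((a, b))] = kab
        region_size[frozenset((a,))] = sizes[a] - kab
        region_size[frozenset((b,))] = sizes[b] - kab
    else:
        a, b, c = names
        t = triple or 0
        kab, kac, kbc = k_of(a, b), k_of(a, c), k_of(b, c)
        if t > min(kab, kac, kbc):
            raise InfeasibleSpecError(
                f"triple intersection {t} exceeds a pairwise overlap "
                f"({a},{b})={kab}, ({a},{c})={kac}, ({b},{c})={kbc}")
        region_size[frozenset((a, b, c))] = t
        region_size[frozenset((a, b))] = kab - t
        region_size[frozenset((a, c))] = kac - t
        region_size[frozenset((b, c))] = kbc - t
        region_size[frozenset((a,))] = sizes[a] - kab - kac + t
        region_size[frozenset((b,))] = sizes[b] - kab - kbc + t
        region_size[frozenset((c,))] = sizes[c] - kac - kbc + t

    bad = {tuple(sorted(sig)): s for sig, s in region_size.items() if s < 0}
    if bad:
        raise InfeasibleSpecError(f"negative Venn region sizes: {bad}")
    total = sum(region_size.values())
    if total > u.size:
        raise InfeasibleSpecError(
            f"planted sets need {total} distinct genes but universe has {u.size}")

    order = rng.permutation(u.size)
    cursor = 0
    members: dict[str, set[str]] = {n: set() for n in names}
    for sig in sorted(region_size, key=lambda s: (len(s), sorted(s))):
        s = region_size[sig]
        block = [pool[i] for i in order[cursor:cursor + s]]
        cursor += s
        for n in sig:
            members[n].update(block)
    sets = {n: GeneSet(name=n, members=frozenset(members[n]),
                       provenance="synthetic (deterministic planting)")
            for n in names}
    truth = {
        "mode": "deterministic",
        "pairs": {f"{x}|{y}": len(sets[x].members & sets[y].members)
                  for x, y in combinations(names, 2)},
        "regions": {"&".join(sorted(sig)): s for sig, s in region_size.items()},
    }
    return sets, truth


def planted_rf_to_k(rf: float, n_a: int, n_b: int, N: int) -> int:
    """Overlap count realising a target representation factor (rounded)."""
    k = int(round(rf * n_a * n_b / N))
    if k > min(n_a, n_b):
        raise InfeasibleSpecError(f"RF {rf} needs k={k} > min({n_a}, {n_b})")
    return k


def gen_expression(
    n_genes: int,
    tissues: Sequence[str],
    planted: Mapping[str, int] | None = None,
    fold: float = 5.0,
    seed: int = 0,
    exact_boundary: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Expression matrix with genes planted as tissue-enriched.

    Background levels are log-normal (right-skewed); for each tissue in
    ``planted``, the stated number of genes get a focal value of
    ``fold * max(other tissues)`` times a random boost >= 1 (or exactly
    ``fold`` times when ``exact_boundary``, probing the inclusive
    threshold).  Truth records the planted (gene, tissue) calls.
    """
    if len(tissues) < 2:
        raise ContractError("need >= 2 tissues")
    if fold <= 1:
        raise ContractError(f"fold must exceed 1, got {fold}")
    planted = dict(planted or {})
    unknown = set(planted) - set(tissues)
    if unknown:
        raise ContractError(f"planted tissues not in matrix: {sorted(unknown)}")
    if sum(planted.values()) > n_genes:
        raise InfeasibleSpecError("more planted genes than genes in the matrix")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:06d}" for i in range(1, n_genes + 1)]
    vals = rng.lognormal(mean=LOGNORMAL_MEAN, sigma=LOGNORMAL_SIGMA,
                         size=(n_genes, len(tissues)))
    df = pd.DataFrame(vals, index=genes, columns=list(tissues))

    truth: dict[str, list[str]] = {t: [] for t in planted}
    pool = rng.permutation(n_genes)
    cursor = 0
    for tissue in sorted(planted):
        for _ in range(planted[tissue]):
            gi = pool[cursor]
            cursor += 1
            gene = genes[gi]
            others = df.loc[gene, [t for t in tissues if t != tissue]]
            mx = float(others.max())
            boost = 1.0 if exact_boundary else float(rng.uniform(1.2, 3.0))
            v = fold * mx * boost
            # fp guard: the planted ratio must clear the inclusive threshold
            while v / mx < fold:
                v = float(np.nextafter(v, np.inf))
            df.loc[gene, tissue] = v
            truth[tissue].append(gene)
    return df, {"planted": {t: sorted(g) for t, g in truth.items()}, "fold": fold}


def gen_annotations(
    reference: GeneSet,
    n_categories: int = 10,
    planted_category: str | None = None,
    planted_fold: float = 1.0,
    n_test: int = 100,
    ontology: str = "synthetic",
    seed: int = 0,
) -> tuple[AnnotationTable, GeneSet, dict]:
    """Annotation table over ``reference`` plus a test list with one
    category optionally inflated to ``planted_fold`` times its base rate.

    Every reference gene gets exactly one of ``n_categories`` equiprobable
    categories.  The test list of ``n_test`` genes is drawn so that the
    planted category's share is ``planted_fold`` times its reference share
    (rounded); fold 1 (or no planted category) draws the test list
    uniformly.
    """
    ref = sorted(reference.members)
    if not ref:
        raise ContractError("reference is empty")
    if n_test > len(ref):
        raise InfeasibleSpecError(f"test size {n_test} exceeds reference {len(ref)}")
    rng = np.random.default_rng(seed)
    cats = [f"C{i:03d}" for i in range(1, n_categories + 1)]
    assignment = rng.integers(0, n_categories, size=len(ref))
    g2c = {g: frozenset({cats[a]}) for g, a in zip(ref, assignment)}
    annot = AnnotationTable(ontology=ontology, gene_to_categories=g2c,
                            labels={c: f"synthetic category {c}" for c in cats})

    if planted_category is None or planted_fold == 1.0:
        idx = rng.choice(len(ref), size=n_test, replace=False)
        test_members = frozenset(ref[i] for i in idx)
        truth = {"planted_category": None, "planted_fold": 1.0}
    else:
        if planted_category not in cats:
            raise ContractError(f"unknown planted category {planted_category!r}")
        in_cat = [g for g in ref if planted_category in g2c[g]]
        out_cat = [g for g in ref if planted_category not in g2c[g]]
        base_p = len(in_cat) / len(ref)
        k_target = int(round(planted_fold * base_p * n_test))
        if k_target > len(in_cat) or n_test - k_target > len(out_cat):
            raise InfeasibleSpecError(
                f"fold {planted_fold} infeasible: needs {k_target} of {len(in_cat)} "
                f"category genes and {n_test - k_target} of {len(out_cat)} others")
        pick_in = rng.choice(len(in_cat), size=k_target, replace=False)
        pick_out = rng.choice(len(out_cat), size=n_test - k_target, replace=False)
        test_members = frozenset(
            [in_cat[i] for i in pick_in] + [out_cat[i] for i in pick_out])
        truth = {"planted_category": planted_category, "planted_fold": planted_fold,
                 "k_planted": k_target, "base_p": base_p}
    test = GeneSet(name="synthetic-test", members=test_members,
                   provenance="synthetic annotation plant")
    return annot, test, truth


def gen_regions(
    chrom_len: int = 10_000_000,
    n_genes: int = 50,
    n_intervals: int = 200,
    min_spacing: int = 20_000,
    interval_len: tuple[int, int] = (100, 1_000),
    basal_up: int = 5_000,
    basal_down: int = 1_000,
    max_ext: int = 1_000_000,
    in_basal_only: bool = False,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[list[GenomicInterval], list[GeneModel], dict[str, int], dict]:
    """One synthetic chromosome of gene models plus random intervals.

    Gene TSSs are uniform with a minimum spacing; strands are random.
    Truth assignments are computed by a quadratic all-pairs scan over the
    basal-plus-extension domains, independent of the interval-tree query
    path.  ``in_basal_only`` restricts interval placement to basal windows
    (every interval then has a non-empty assignment).
    """
    if (n_genes - 1) * min_spacing >= chrom_len:
        raise InfeasibleSpecError("minimum gene spacing infeasible for chromosome length")
    rng = np.random.default_rng(seed)
    # sorted draws on the shrunk lattice, then re-inflate -> min spacing holds
    slots = np.sort(rng.choice(chrom_len - (n_genes - 1) * min_spacing,
                               size=n_genes, replace=False))
    tss = slots + np.arange(n_genes) * min_spacing
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = [GeneModel(symbol=f"SG{i:04d}", chrom=chrom, tss=int(t), strand=s)
             for i, (t, s) in enumerate(zip(tss, strands), start=1)]
    chrom_sizes = {chrom: chrom_len}
    domains = basal_extension_domains(genes, chrom_sizes, basal_up=basal_up,
                                      basal_down=basal_down, max_ext=max_ext)

    lo, hi = interval_len
    intervals: list[GenomicInterval] = []
    for i in range(1, n_intervals + 1):
        length = int(rng.integers(lo, hi + 1))
        if in_basal_only:
            g = genes[int(rng.integers(0, n_genes))]
            b_lo = max(0, g.tss - (basal_up if g.strand == "+" else basal_down))
            start = min(b_lo, chrom_len - length)
        else:
            start = int(rng.integers(0, chrom_len - length))
        intervals.append(GenomicInterval(chrom=chrom, start=start,
                                         end=start + length, id=f"IV{i:05d}"))

    truth_assign = [
        sorted(d.symbol for d in domains
               if d.chrom == iv.chrom and d.start < iv.end and iv.start < d.end)
        for iv in intervals
    ]
    truth = {"assignments": {iv.id: genes_ for iv, genes_ in zip(intervals, truth_assign)}}
    return intervals, genes, chrom_sizes, truth


def write_dataset(
    out_dir: str | Path,
    sets: Mapping[str, GeneSet] | None = None,
    expression: pd.DataFrame | None = None,
    intervals: Sequence[GenomicInterval] | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    truth: dict | None = None,
) -> None:
    """Write generated inputs in the same plain-text formats the pipeline
    reads, plus a truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sets:
        for name, gs in sets.items():
            (out / f"{name}.txt").write_text("\n".join(sorted(gs.members)) + "\n")
    if expression is not None:
        expression.to_csv(out / "expression.tsv", sep="\t")
    if intervals is not None:
        write_bed(intervals, out / "intervals.bed")
    if gene_models is not None:
        write_gene_models(gene_models, out / "gene_models.tsv")
    if chrom_sizes is not None:
        (out / "chrom.sizes").write_text(
            "\n".join(f"{c}\t{s}" for c, s in chrom_sizes.items()) + "\n")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
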