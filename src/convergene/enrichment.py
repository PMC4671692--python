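"""Category overrepresentation by the binomial test.

Given a test gene list drawn from a reference list, and an annotation table
mapping genes to categories (GO-style classes, pathways, protein classes),
each category's test-list count k is compared with the expectation
n_test * p_ref, where p_ref is the category's share of annotated reference
genes.  Significance is the binomial upper tail P(X >= k),
X ~ Binomial(n_test, p_ref), corrected for the number of categories tested
(Bonferroni by default, Benjamini-Hochberg selectable).

Genes absent from the annotation table are excluded from n_test; multi-label
genes count once in every category they carry.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ContractError
from .genesets import GeneSet

logger = logging.getLogger(__name__)

_CORRECTIONS = {"bonferroni", "bh", "none"}


@dataclass(frozen=True)
class AnnotationTable:
    """One ontology: gene -> categories, with optional display labels."""

    ontology: str
    gene_to_categories: dict[str, frozenset[str]]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        for g, cats in self.gene_to_categories.items():
            if not cats:
                raise ContractError(f"gene {g!r} annotated with zero categories")

    @property
    def categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.gene_to_categories.values():
            out |= cats
        return out

    def label(self, category: str) -> str:
        return self.labels.get(category, category)


def load_annotation_tsv(path: str | Path, ontology: str | None = None,
                        label_path: str | Path | None = None) -> AnnotationTable:
    """Read a two-column (gene, category_id) TSV; labels from an optional
    (category_id, label) TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).dropna()
    if df.shape[1] < 2:
        raise ContractError(f"{path}: annotation TSV needs (gene, category) columns")
    g2c: dict[str, set[str]] = {}
    for gene, cat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        g2c.setdefault(gene.strip().upper(), set()).add(cat.strip())
    labels: dict[str, str] = {}
    if label_path is not None:
        ldf = pd.read_csv(label_path, sep="\t", dtype=str).dropna()
        labels = dict(zip(ldf.iloc[:, 0], ldf.iloc[:, 1]))
    return AnnotationTable(
        ontology=ontology or path.stem,
        gene_to_categories={g: frozenset(c) for g, c in g2c.items()},
        labels=labels,
    )


def load_annotation_gmt(path: str | Path, ontology: str | None = None) -> AnnotationTable:
    """Read GMT (one category per line: id <tab> description <tab> genes...)."""
    path = Path(path)
    g2c: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ContractError(f"{path}: malformed GMT line {line[:50]!r}")
        cat, desc, genes = parts[0], parts[1], parts[2:]
        labels[cat] = desc
        for g in genes:
            if g.strip():
                g2c.setdefault(g.strip().upper(), set()).add(cat)
    return AnnotationTable(
        ontology=ontology or path.stem,
        gene_to_categories={g: frozenset(c) for g, c in g2c.items()},
        labels=labels,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's overrepresentation outcome."""

    category: str
    label: str
    n_test: int
    k_test: int
    p_ref: float
    expected: float
    fold: float
    p_raw: float
    p_adj: float
    direction: str  # "over" | "under"

    def to_dict(self) -> dict:
        return {
            "category": self.category, "label": self.label,
            "n_test": self.n_test, "k_test": self.k_test,
            "p_ref": self.p_ref, "expected": self.expected, "fold": self.fold,
            "p_raw": self.p_raw, "p_adj": self.p_adj, "direction": self.direction,
        }


def _adjust(p_raw: Sequence[float], method: str) -> list[float]:
    if not p_raw:
        return []
    if method == "bonferroni":
        m = len(p_raw)
        return [min(1.0, m * p) for p in p_raw]
    if method == "bh":
        return list(multipletests(p_raw, method="fdr_bh")[1])
    if method == "none":
        return list(p_raw)
    raise ContractError(f"unknown correction {method!r}; choose from {sorted(_CORRECTIONS)}")


def binomial_enrichment(
    test: GeneSet,
    reference: GeneSet,
    annot: AnnotationTable,
    correction: str = "bonferroni",
    include_under: bool = False,
) -> list[EnrichmentResult]:
    """Binomial overrepresentation of ``test`` against ``reference``.

    Test genes outside the reference are dropped (with a logged count);
    genes missing from the annotation table are excluded from ``n_test``.
    Categories with k_test = 0 are omitted unless ``include_under`` is set,
    in which case they are reported with direction="under" and the lower
    tail.  Results are sorted by adjusted then raw p.
    """
    if correction not in _CORRECTIONS:
        raise ContractError(f"unknown correction {correction!r}; choose from {sorted(_CORRECTIONS)}")

    stray = test.members - reference.members
    if stray:
        logger.warning(
            "%d test genes not in reference %r dropped from test list %r",
            len(stray), reference.name, test.name,
        )
    test_members = test.members & reference.members

    annotated = set(annot.gene_to_categories)
    ref_annot = reference.members & annotated
    if not ref_annot:
        raise ContractError(
            f"reference {reference.name!r} has no gene annotated in ontology {annot.ontology!r}"
        )
    test_annot = test_members & annotated
    n_test = len(test_annot)
    n_dropped = len(test_members) - n_test
    if n_dropped:
        logger.info("%d test genes unannotated in %s excluded from n_test",
                    n_dropped, annot.ontology)
    if n_test == 0:
        logger.warning("test list %r has no annotated gene in %s; empty result",
                       test.name, annot.ontology)
        return []

    ref_count: dict[str, int] = {}
    for g in ref_annot:
        for c in annot.gene_to_categories[g]:
            ref_count[c] = ref_count.get(c, 0) + 1
    test_count: dict[str, int] = {}
    for g in test_annot:
        for c in annot.gene_to_categories[g]:
            test_count[c] = test_count.get(c, 0) + 1

    rows: list[dict] = []
    for cat, r_c in sorted(ref_count.items()):
        k = test_count.get(cat, 0)
        if k == 0 and not include_under:
            continue
        p_ref = r_c / len(ref_annot)
        expected = n_test * p_ref
        direction = "over" if k >= expected else "under"
        if include_under and direction == "under":
            p_raw = float(binom.cdf(k, n_test, p_ref))  # P(X <= k)
        else:
            p_raw = float(binom.sf(k - 1, n_test, p_ref))  # P(X >= k)
        rows.append({
            "category": cat, "label": annot.label(cat), "n_test": n_test,
            "k_test": k, "p_ref": p_ref, "expected": expected,
            "fold": k / expected, "p_raw": min(1.0, p_raw), "direction": direction,
        })

    p_adj = _adjust([r["p_raw"] for r in rows], correction)
    results = [
        EnrichmentResult(p_adj=min(1.0, max(pa, r["p_raw"])), **r)
        for r, pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.category))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["category", "label", "n_test", "k_test", "p_ref", "expected",
            "fold", "p_raw", "p_adj", "direction"]
    return pd.DataFrame([r.to_dict() for r in results], columns=cols)


def enrichment_battery(
    overlap_sets: Mapping[str, GeneSet],
    reference_map: Mapping[str, GeneSet],
    annots: Iterable[AnnotationTable],
    correction: str = "bonferroni",
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run :func:`binomial_enrichment` for every (set, ontology) pair.

    ``reference_map`` names the reference list for each overlap set; a
    missing mapping is a configuration error naming the set.
    """
    annots = list(annots)
    missing = [name for name in overlap_sets if name not in reference_map]
    if missing:
        raise ConfigError([f"no reference mapped for overlap set {name!r}" for name in missing])
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for name, gs in overlap_sets.items():
        for annot in annots:
            res = binomial_enrichment(gs, reference_map[name], annot, correction=correction)
            out[(name, annot.ontology)] = results_to_frame(res)
    return out
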