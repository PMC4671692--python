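"""Tissue-enrichment calling from a genes x tissues expression matrix.

A gene is *enriched* in its top-expressing (focal) tissue when the focal
level is at least ``fold`` times the maximum level over all other tissues
(the Protein-Atlas-style "at least 5X higher than all other tissues" rule;
the threshold is inclusive).  Tissues are eligible for downstream overlap
analysis only when they carry at least ``min_genes`` enriched genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .genesets import GeneSet

#: Pseudocount floor for the denominator, in matrix units; an all-zero gene
#: gets ratio 0 and is never enriched.
EPSILON = 1e-6


@dataclass(frozen=True)
class TissueCall:
    gene: str
    tissue: str
    ratio: float
    enriched: bool


def validate_matrix(m: pd.DataFrame) -> None:
    if m.shape[1] < 2:
        raise ContractError("expression matrix needs >= 2 tissues")
    if m.index.has_duplicates:
        raise ContractError("gene identifiers must be unique")
    if (m.values < 0).any():
        raise ContractError("expression values must be non-negative")


def load_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes as rows, tissues as columns, header row of tissue names."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    validate_matrix(m)
    return m


def call_tissue_enriched(
    m: pd.DataFrame,
    fold: float = 5.0,
    denominator: str = "max",
    eps: float = EPSILON,
) -> list[TissueCall]:
    """Assign each gene a focal tissue (its argmax) and an enrichment verdict.

    Parameters
    ----------
    m
        Non-negative genes x tissues matrix (pandas DataFrame).
    fold
        Inclusive enrichment threshold; default 5 (the "at least 5X" rule).
    denominator
        "max" (default) compares the focal level with the *maximum* over
        the other tissues; "mean" is available for sensitivity analysis.
    eps
        Floor for the denominator so a zero background cannot divide out;
        the comparison is focal / max(other, eps).

    Argmax ties break to the lexicographically smallest tissue name.
    """
    validate_matrix(m)
    if denominator not in ("max", "mean"):
        raise ContractError(f"denominator must be 'max' or 'mean', got {denominator!r}")
    cols = sorted(m.columns)
    vals = m[cols].to_numpy(dtype=float)
    focal_idx = vals.argmax(axis=1)  # first occurrence -> lexicographic tie-break
    calls: list[TissueCall] = []
    n_t = len(cols)
    for i, gene in enumerate(m.index):
        j = focal_idx[i]
        focal = vals[i, j]
        others = np.delete(vals[i], j)
        base = others.max() if denominator == "max" else others.mean()
        ratio = focal / max(base, eps) if n_t > 1 else 0.0
        if focal == 0.0:
            ratio = 0.0  # all-zero gene is never enriched
        calls.append(TissueCall(gene=str(gene), tissue=cols[j],
                                ratio=float(ratio), enriched=bool(ratio >= fold)))
    return calls


def calls_to_frame(calls: Sequence[TissueCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": c.gene, "tissue": c.tissue, "ratio": c.ratio, "enriched": c.enriched}
         for c in calls],
        columns=["gene", "tissue", "ratio", "enriched"],
    )


def eligible_tissues(
    calls: Sequence[TissueCall], min_genes: int = 5
) -> dict[str, GeneSet]:
    """Tissues with >= ``min_genes`` enriched genes, each as a GeneSet."""
    by_tissue: dict[str, set[str]] = {}
    for c in calls:
        if c.enriched:
            by_tissue.setdefault(c.tissue, set()).add(c.gene)
    return {
        t: GeneSet(name=t, members=frozenset(genes), provenance="tissue-enrichment call")
        for t, genes in sorted(by_tissue.items())
        if len(genes) >= min_genes
    }
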