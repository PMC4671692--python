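"""Config-driven orchestration of the convergence analysis.

``run_convergence`` reproduces the full experimental scheme on membership
lists: every evolution-list x {expression, tissue, phenotype}-list pairwise
overlap, the union ("total unique fast evolving") summaries, Venn
partitions, and the category-enrichment battery, with TSV + JSON mirrors
and a run manifest.  ``count_mode_report`` reproduces published overlap
arithmetic from counts alone, with conformance flags where printed values
disagree with the computed ones.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .conformance import ConformanceFlag, check_report, write_flags
from .enrichment import enrichment_battery, load_annotation_gmt, load_annotation_tsv
from .errors import ConfigError, ContractError
from .genesets import DEFAULT_UNIVERSE_SIZE, GeneSet, GeneUniverse, load_gene_list
from .overlap import (OverlapResult, overlap, overlap_counts, round_half_away,
                      union_overlap, venn_partition, write_results)

logger = logging.getLogger(__name__)

ROLES = ("evolution", "expression", "phenotype", "tissue")


def load_reference_counts() -> pd.DataFrame:
    """The packaged published overlap counts (fast-evolving gene lists vs
    placental / tissue-enriched / preterm-birth expression lists, N=19,814),
    including the printed one-decimal RFs and percentage columns."""
    with resources.files("convergene.data").joinpath("reference_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def count_mode_report(
    counts: pd.DataFrame, N: int = DEFAULT_UNIVERSE_SIZE
) -> tuple[pd.DataFrame, list[ConformanceFlag]]:
    """Overlap statistics from a table of counts alone.

    ``counts`` needs columns name_a, n_a, name_b, n_b, k; optional columns
    rf_printed / pct_printed / pct_base ("a" or "b") / k_alt feed the
    conformance check.  Returns the enriched report plus the flags for
    every printed value that disagrees with the computed one.
    """
    required = {"name_a", "n_a", "name_b", "n_b", "k"}
    missing = required - set(counts.columns)
    if missing:
        raise ContractError(f"count table missing columns: {sorted(missing)}")
    rows = []
    for _, r in counts.iterrows():
        res = overlap_counts(int(r["n_a"]), int(r["n_b"]), int(r["k"]), N,
                             name_a=str(r["name_a"]), name_b=str(r["name_b"]))
        row = res.to_dict()
        base = r.get("pct_base")
        if isinstance(base, str) and base in ("a", "b"):
            denom = res.n_a if base == "a" else res.n_b
            row["pct"] = round_half_away(100.0 * res.k / denom, 1)
        else:
            row["pct"] = float("nan")
        for extra in ("group", "rf_printed", "pct_printed", "k_alt"):
            if extra in counts.columns:
                row[extra] = r[extra]
        rows.append(row)
    report = pd.DataFrame(rows)
    return report, check_report(report)


@dataclass(frozen=True)
class GeneListEntry:
    name: str
    path: str
    role: str


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one convergence run."""

    gene_lists: tuple[GeneListEntry, ...]
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    annotations: tuple[str, ...] = ()
    reference_map: Mapping[str, str] = field(default_factory=dict)
    p_threshold: float = 0.05
    out_dir: str = "convergene-out"
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, reporting *all* violations."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return validate_config(raw, base_dir=Path(path).parent)


def validate_config(raw: dict, base_dir: Path | None = None) -> RunConfig:
    problems: list[str] = []
    base = base_dir or Path(".")
    entries: list[GeneListEntry] = []
    gene_lists = raw.get("gene_lists", [])
    if not gene_lists:
        problems.append("no gene_lists configured")
    for i, e in enumerate(gene_lists):
        name, p, role = e.get("name"), e.get("path"), e.get("role")
        if not name:
            problems.append(f"gene_lists[{i}]: missing name")
        if role not in ROLES:
            problems.append(f"gene_lists[{i}] ({name}): role {role!r} not in {ROLES}")
        if not p:
            problems.append(f"gene_lists[{i}] ({name}): missing path")
        else:
            p = str((base / p) if not Path(p).is_absolute() else Path(p))
            if not Path(p).exists():
                problems.append(f"gene_lists[{i}] ({name}): path {p} does not exist")
        if name and p and role in ROLES:
            entries.append(GeneListEntry(name=str(name), path=str(p), role=str(role)))
    annots = []
    for a in raw.get("annotations", []):
        ap = str((base / a) if not Path(a).is_absolute() else Path(a))
        if not Path(ap).exists():
            problems.append(f"annotation file {ap} does not exist")
        else:
            annots.append(ap)
    universe_size = int(raw.get("universe_size", DEFAULT_UNIVERSE_SIZE))
    if universe_size < 1:
        problems.append(f"universe_size must be >= 1, got {universe_size}")
    names = [e.name for e in entries]
    if len(names) != len(set(names)):
        problems.append("gene list names must be unique")
    ref_map = dict(raw.get("reference_map", {}))
    for tgt, ref in ref_map.items():
        if ref not in names:
            problems.append(f"reference_map[{tgt!r}] points to unknown list {ref!r}")
    if problems:
        raise ConfigError(problems)
    return RunConfig(
        gene_lists=tuple(entries),
        universe_size=universe_size,
        annotations=tuple(annots),
        reference_map=ref_map,
        p_threshold=float(raw.get("p_threshold", 0.05)),
        out_dir=str(raw.get("out_dir", "convergene-out")),
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_convergence(config: RunConfig) -> Path:
    """Execute the full convergence scheme; returns the output directory.

    Outputs: pairwise_overlaps.tsv/.json (every evolution x other-role
    pair, flagged "overrepresented" when RF > 1 at the p threshold),
    union_overlaps.tsv (the "total unique fast evolving" summaries), one
    Venn TSV per partition, per-(set, ontology) enrichment TSVs, a
    structured run.log and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("convergene")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        universe = GeneUniverse(size=config.universe_size)
        sets: dict[str, GeneSet] = {}
        by_role: dict[str, list[GeneSet]] = {r: [] for r in ROLES}
        for e in config.gene_lists:
            gs = load_gene_list(e.path, name=e.name)
            sets[e.name] = gs
            by_role[e.role].append(gs)

        evolution = by_role["evolution"]
        targets = by_role["expression"] + by_role["tissue"] + by_role["phenotype"]

        pairwise: list[OverlapResult] = []
        for tgt in targets:
            for evo in evolution:
                pairwise.append(overlap(tgt, evo, universe))
        pair_df = pd.DataFrame([r.to_dict() for r in pairwise])
        if not pair_df.empty:
            pair_df["overrepresented"] = (pair_df["rf"] > 1.0) & \
                (pair_df["p_upper"] < config.p_threshold)
        write_results(pairwise, out / "pairwise_overlaps.tsv",
                      out / "pairwise_overlaps.json")
        if not pair_df.empty:
            pair_df.to_csv(out / "pairwise_overlaps.tsv", sep="\t", index=False)

        unions = []
        if evolution:
            for tgt in targets:
                unions.append(union_overlap(tgt, evolution, universe))
        if unions:
            udf = pd.DataFrame([u.to_dict() for u in unions])
            udf.to_csv(out / "union_overlaps.tsv", sep="\t", index=False)

        venn_dir = out / "venn"
        venn_dir.mkdir(exist_ok=True)
        if 1 <= len(evolution) <= 3:
            for tgt in by_role["phenotype"]:
                part = venn_partition([tgt] + evolution)
                part.to_frame().to_csv(venn_dir / f"{tgt.name}_vs_evolution.tsv",
                                       sep="\t", index=False)
        phen = by_role["phenotype"]
        if 2 <= len(phen) <= 4:
            part = venn_partition(phen)
            part.to_frame().to_csv(venn_dir / "phenotypes.tsv", sep="\t", index=False)

        if config.annotations and config.reference_map:
            annots = []
            for a in config.annotations:
                loader = load_annotation_gmt if a.endswith(".gmt") else load_annotation_tsv
                annots.append(loader(a))
            overlap_sets = {n: sets[n] for n in config.reference_map if n in sets}
            ref_map = {n: sets[r] for n, r in config.reference_map.items() if n in sets}
            battery = enrichment_battery(overlap_sets, ref_map, annots)
            enr_dir = out / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            for (name, onto), df in battery.items():
                df.to_csv(enr_dir / f"{name}__{onto}.tsv", sep="\t", index=False)

        manifest = {
            "version": __version__,
            "universe_size": config.universe_size,
            "seed": config.seed,
            "p_threshold": config.p_threshold,
            "inputs": [
                {"name": e.name, "role": e.role, "path": e.path,
                 "sha256": _sha256(e.path), "n_members": len(sets[e.name]),
                 "n_raw": sets[e.name].n_raw}
                for e in config.gene_lists
            ],
            "annotations": [{"path": a, "sha256": _sha256(a)} for a in config.annotations],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def write_count_mode_outputs(
    report: pd.DataFrame, flags: Sequence[ConformanceFlag], out_dir: str | Path
) -> Path:
    """Persist a count-mode report: TSV, full-precision JSON, conformance log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "count_mode_report.tsv", sep="\t", index=False)
    (out / "count_mode_report.json").write_text(
        report.to_json(orient="records", indent=1))
    write_flags(flags, out / "conformance.log")
    return out
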