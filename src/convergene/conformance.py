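"""Printed-versus-computed conformance checks.

When a published overlap table is re-typed as count-mode input it can carry
the values the source printed (one-decimal RFs, percentage columns, or an
alternative count quoted elsewhere in the same source).  The engine always
reports its *computed* values; this module compares them with the printed
ones and flags every disagreement instead of forcing agreement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConformanceFlag:
    """One printed value that disagrees with the computed one."""

    row: str           # "name_a x name_b"
    kind: str          # "rf" | "pct" | "count"
    printed: float
    computed: float
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.row}: {self.message}"


def check_report(report: pd.DataFrame) -> list[ConformanceFlag]:
    """Compare a count-mode report against its printed columns.

    Recognised optional columns: ``rf_printed``, ``pct_printed`` (with the
    computed ``pct`` column present), and ``k_alt`` (an alternative overlap
    count quoted elsewhere for the same cell).  Returns one flag per
    disagreement; every flag is also logged.
    """
    flags: list[ConformanceFlag] = []
    for _, r in report.iterrows():
        row = f"{r['name_a']} x {r['name_b']}"
        if "rf_printed" in report.columns and pd.notna(r.get("rf_printed")):
            printed, computed = float(r["rf_printed"]), float(r["rf_reported"])
            if printed != computed:
                flags.append(ConformanceFlag(
                    row=row, kind="rf", printed=printed, computed=computed,
                    message=(f"printed RF {printed} disagrees with computed "
                             f"{computed} (full precision {r['rf']:.4f})"),
                ))
        if "pct_printed" in report.columns and pd.notna(r.get("pct_printed")) \
                and pd.notna(r.get("pct")):
            printed, computed = float(r["pct_printed"]), float(r["pct"])
            if printed != computed:
                flags.append(ConformanceFlag(
                    row=row, kind="pct", printed=printed, computed=computed,
                    message=f"printed percentage {printed} disagrees with computed {computed}",
                ))
        if "k_alt" in report.columns and pd.notna(r.get("k_alt")):
            k, k_alt = int(r["k"]), int(r["k_alt"])
            if k != k_alt:
                flags.append(ConformanceFlag(
                    row=row, kind="count", printed=float(k_alt), computed=float(k),
                    message=(f"source quotes both {k} and {k_alt} for this overlap; "
                             f"the tabulated count {k} was used"),
                ))
    for f in flags:
        logger.warning("conformance: %s", f)
    return flags


def write_flags(flags: Sequence[ConformanceFlag], path: str | Path) -> None:
    lines = [str(f) for f in flags] or ["no printed-vs-computed disagreements"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
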