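"""Summary tabulation of modification classes by fold-change category.

The central product is a table with one column per peptide category —
total detected, total quantified, no change, fold increase >1, fold
increase >2, fold decrease <1, fold decrease <0.5 — and one row per
oxidative class (plus the total). The >2 and <0.5 columns are subsets of
the >1 and <1 columns, and the quantified column partitions exactly into
no-change + increase>1 + decrease<1. Percentages are per column (class
count over the column's total-peptides count), rounded half-up to one
decimal.

Also here: the residue x modification-class site matrix (localized sites
only; ambiguous sites are excluded rather than fractionally attributed,
and cells where a class never searches a residue are marked unavailable),
and a volcano-plot data export (log2 fold change vs -log10 adjusted p).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import ModificationRegistry, default_registry
from .quant import PeptideQuantRecord, QuantResult, QuantRun

__all__ = [
    "CLASS_ROWS",
    "SUMMARY_COLUMNS",
    "ModificationSummary",
    "ResidueModMatrix",
    "percent_half_up",
    "summarize_modifications",
    "residue_mod_matrix",
    "volcano_export",
]

CLASS_ROWS = ("carbonylated", "hydroxylated", "dioxidized", "trioxidized")
SUMMARY_COLUMNS = (
    "total_detected",
    "total_quantified",
    "no_change",
    "increase_gt1",
    "increase_gt2",
    "decrease_lt1",
    "decrease_lt05",
)

_CLASS_TO_MOD = {
    "carbonylated": "carbonylation",
    "hydroxylated": "oxidation",
    "dioxidized": "dioxidation",
    "trioxidized": "trioxidation",
}

RESIDUES_20 = tuple("ACDEFGHIKLMNPQRSTVWY")


def percent_half_up(count: int, total: int) -> float | None:
    """Percent of ``count`` in ``total``, rounded half-up to 1 decimal.

    Returns None for a zero denominator (reported as N/A).
    """
    if total == 0:
        return None
    value = (Decimal(count) * 100) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ModificationSummary:
    """Counts and percentages per oxidative class per category column.

    ``counts`` has rows ``total`` + the four classes; ``percents`` has the
    four class rows with NaN where the column total is zero.
    """

    counts: pd.DataFrame
    percents: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ModificationSummary":
        """Derive percentages from a counts table using the half-up rule.

        ``counts`` must be indexed by ``total`` + class rows with the
        summary columns; this is also the path for recomputing published
        percentage cells from their printed counts.
        """
        counts = counts.loc[["total", *CLASS_ROWS], list(SUMMARY_COLUMNS)].astype(int)
        percents = pd.DataFrame(index=list(CLASS_ROWS), columns=list(SUMMARY_COLUMNS), dtype=float)
        for col in SUMMARY_COLUMNS:
            total = int(counts.at["total", col])
            for row in CLASS_ROWS:
                p = percent_half_up(int(counts.at[row, col]), total)
                percents.at[row, col] = np.nan if p is None else p
        return cls(counts=counts, percents=percents)

    def render_text(self) -> str:
        """Aligned text rendering of counts and percent rows."""
        lines = [self.counts.to_string()]
        pct = self.percents.map(lambda v: "N/A" if pd.isna(v) else f"{v:.1f}%")
        pct.index = [f"% {r}" for r in pct.index]
        lines.append(pct.to_string())
        return "\n\n".join(lines)


def _category_membership(result: QuantResult) -> list[str]:
    cols = ["total_quantified"]
    cat = result.category
    if cat == "no_change":
        cols.append("no_change")
    elif cat in ("increase_gt1", "increase_gt2"):
        cols.append("increase_gt1")
        if cat == "increase_gt2":
            cols.append("increase_gt2")
    elif cat in ("decrease_lt1", "decrease_lt05"):
        cols.append("decrease_lt1")
        if cat == "decrease_lt05":
            cols.append("decrease_lt05")
    return cols


def summarize_modifications(
    run_or_results: QuantRun | Sequence[QuantResult],
    detected_only: Sequence[PeptideQuantRecord] | None = None,
) -> ModificationSummary:
    """Tabulate counts/percentages per class per category column.

    Accepts a :class:`QuantRun` (its detected-only records feed the
    detected column) or a bare result list, optionally with extra
    detected-but-not-quantified records. The detected column is the
    quantified peptides plus those extra records, so it can exceed the
    quantified column.
    """
    if isinstance(run_or_results, QuantRun):
        results = run_or_results.results
        detected_only = list(run_or_results.detected_only) + list(detected_only or [])
    else:
        results = list(run_or_results)
        detected_only = list(detected_only or [])

    counts = pd.DataFrame(
        0, index=["total", *CLASS_ROWS], columns=list(SUMMARY_COLUMNS), dtype=int
    )
    for res in results:
        cols = _category_membership(res) + ["total_detected"]
        for col in cols:
            counts.at["total", col] += 1
            for cls in CLASS_ROWS:
                if getattr(res.flags, cls):
                    counts.at[cls, col] += 1
    from .chem import classify_oxidative_state

    for rec in detected_only:
        counts.at["total", "total_detected"] += 1
        flags = classify_oxidative_state(rec.mods)
        for cls in CLASS_ROWS:
            if getattr(flags, cls):
                counts.at[cls, "total_detected"] += 1
    return ModificationSummary.from_counts(counts)


@dataclass
class ResidueModMatrix:
    """Residue x oxidative-class counts of localized modification sites.

    ``matrix`` has 20 residue rows and 4 class columns; NaN marks cells
    where the residue is never searched for that class.
    """

    matrix: pd.DataFrame

    def total_row(self) -> pd.Series:
        return self.matrix.sum(axis=0, skipna=True)

    def render_text(self) -> str:
        return self.matrix.map(lambda v: "N/A" if pd.isna(v) else str(int(v))).to_string()


def residue_mod_matrix(
    results: Sequence[QuantResult],
    registry: ModificationRegistry | None = None,
) -> ResidueModMatrix:
    """Count localized oxidative-modification sites per residue.

    Callers filter ``results`` to the category of interest first (e.g.
    significant increases). Only annotations with a single resolved
    integer site contribute; ambiguous candidate sets are excluded.
    N-terminal (non-residue) sites do not contribute.
    """
    registry = registry or default_registry()
    matrix = pd.DataFrame(
        np.nan, index=list(RESIDUES_20), columns=list(CLASS_ROWS), dtype=float
    )
    for cls in CLASS_ROWS:
        allowed = registry[_CLASS_TO_MOD[cls]].allowed_residues
        for aa in RESIDUES_20:
            if aa in allowed:
                matrix.at[aa, cls] = 0.0
    mod_to_class = {v: k for k, v in _CLASS_TO_MOD.items()}
    for res in results:
        for ann in res.mods:
            cls = mod_to_class.get(ann.mod_name)
            if cls is None:
                continue
            site = ann.resolved_site
            if not isinstance(site, int):
                continue
            residue = res.peptide[site - 1]
            matrix.at[residue, cls] += 1
    return ResidueModMatrix(matrix=matrix)


def volcano_export(
    results: Sequence[QuantResult], neg_log10_ceiling: float = 16.0
) -> pd.DataFrame:
    """Plot-ready volcano data: log2 fold change vs -log10 adjusted p.

    Adjusted p-values of zero would map to infinity; they are capped at
    ``neg_log10_ceiling`` (default 16, i.e. p = 1e-16).
    """
    if not results:
        raise ValueError("no results to export")
    from .io import format_mods

    rows = []
    for r in results:
        neg = (
            neg_log10_ceiling
            if r.adj_p_value <= 0
            else min(-float(np.log10(r.adj_p_value)), neg_log10_ceiling)
        )
        rows.append(
            {
                "peptide": r.peptide,
                "accession": r.accession,
                "mods": format_mods(r.mods),
                "log2_fold_change": float(np.log2(r.fold_change)),
                "neg_log10_adj_p": neg,
                "category": r.category,
                **r.flags.as_dict(),
            }
        )
    return pd.DataFrame(rows)
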