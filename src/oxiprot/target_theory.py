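"""Relative absolute mass (RAM): a target-theory score for proteins.

Target theory posits that larger, more abundant molecules intercept more
of the short-lived reactive oxygen species produced by water radiolysis.
RAM condenses both factors into one score per protein:

    RAM = log10(copies_per_cell x molecular_weight_kDa)

Molecular weight stands in for surface area (hydration-sphere size) and
copy number for how many such targets the cell presents. On this scale a
typical bacterial proteome centres near 4 and the most abundant large
proteins (e.g. elongation factor Tu) reach ~7. The log base and mass
unit are conventions; comparisons within one catalog are invariant to
consistent unit rescaling because the additive constant cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import two_tailed_t_test

__all__ = [
    "ProteinAbundanceEntry",
    "ram_value",
    "compare_ram_distributions",
    "load_catalog",
    "attach_ram",
]


@dataclass(frozen=True)
class ProteinAbundanceEntry:
    """One catalog row. ``ram`` is None when abundance is unknown."""

    accession: str
    copies_per_cell: float | None
    molecular_weight_kda: float
    ram: float | None = None

    def __post_init__(self) -> None:
        if self.copies_per_cell is not None and self.ram is None:
            object.__setattr__(
                self, "ram", ram_value(self.copies_per_cell, self.molecular_weight_kda)
            )


def ram_value(copies_per_cell, molecular_weight_kda, log_base: float = 10.0):
    """RAM score: log of (copy number x molecular weight in kDa).

    Monotone increasing in both arguments; scalar or array inputs.
    Raises for non-positive values.
    """
    copies = np.asarray(copies_per_cell, dtype=float)
    mw = np.asarray(molecular_weight_kda, dtype=float)
    if np.any(copies <= 0) or np.any(mw <= 0):
        raise ValueError("copies_per_cell and molecular weight must be > 0")
    out = np.log(copies * mw) / np.log(log_base)
    return float(out) if out.ndim == 0 else out


def compare_ram_distributions(
    group_a, group_b, equal_var: bool = True
) -> tuple[float, float, float]:
    """Compare two RAM distributions by a two-tailed Student's t-test.

    Returns (mean_a, mean_b, p_value). Each group needs n >= 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 RAM values")
    p = two_tailed_t_test(a, b, equal_var=equal_var)
    return float(a.mean()), float(b.mean()), p


def load_catalog(path) -> pd.DataFrame:
    """Read a protein-abundance catalog TSV.

    Expected columns: ``accession``, ``copies_per_cell``, ``mw_kda``.
    Adds a ``ram`` column; entries with missing abundance get NaN RAM.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "copies_per_cell", "mw_kda"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    valid = df["copies_per_cell"].notna() & (df["copies_per_cell"] > 0) & (df["mw_kda"] > 0)
    df["ram"] = np.nan
    df.loc[valid, "ram"] = ram_value(
        df.loc[valid, "copies_per_cell"].to_numpy(), df.loc[valid, "mw_kda"].to_numpy()
    )
    return df


def attach_ram(results_frame: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Left-join per-peptide results to catalog RAM values by accession."""
    return results_frame.merge(
        catalog[["accession", "ram"]], on="accession", how="left"
    )
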