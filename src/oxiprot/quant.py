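"""Core peptide-level differential abundance inference for TMT data.

Pipeline order (as :func:`run_quant` applies it):

1. co-isolation interference filter (keep peptides with <= 30% by default);
2. split into *quantified* peptides (all 10 reporter channels present) and
   *detected-only* peptides (any channel missing);
3. per-channel normalization to equal total reporter signal;
4. per-peptide fold change (mean treated / mean control) and two-tailed
   two-sample t-test;
5. Benjamini–Hochberg adjustment across all quantified peptides;
6. fold-change categorization at adjusted p < alpha and oxidative-class
   flag attachment.

The t-test defaults to the pooled-variance Student form (spreadsheet
T.TEST type 2 convention, appropriate for the balanced 5+5 design) with a
switch for Welch. Degenerate inputs where both groups have zero variance
use the conventions p = 1 for equal means and p = 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chem import ModAnnotation, OxidationClassFlags, classify_oxidative_state

__all__ = [
    "TMTDesign",
    "PeptideQuantRecord",
    "QuantResult",
    "QuantConfig",
    "QuantRun",
    "CATEGORIES",
    "ZeroTotalChannelError",
    "UndefinedRatioError",
    "default_design",
    "filter_coisolation",
    "normalize_channels",
    "fold_change",
    "two_tailed_t_test",
    "bh_adjust",
    "categorize_peptide",
    "run_quant",
]

CATEGORIES = ("no_change", "increase_gt1", "increase_gt2", "decrease_lt1", "decrease_lt05")

DEFAULT_CHANNELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131")


class ZeroTotalChannelError(ValueError):
    """A reporter channel with zero total signal cannot be normalized."""


class UndefinedRatioError(ValueError):
    """Fold change is undefined when the control mean is zero."""


@dataclass(frozen=True)
class TMTDesign:
    """Assignment of TMT reporter channels to the two experimental groups.

    The default is the study layout: channels 126–128C carry the five
    mock-treated (control) replicates and 129N–131 the five irradiated
    (treated) replicates.
    """

    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    group_assignment: Mapping[str, str] = field(
        default_factory=lambda: {
            **{c: "control" for c in DEFAULT_CHANNELS[:5]},
            **{c: "treated" for c in DEFAULT_CHANNELS[5:]},
        }
    )

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if set(self.group_assignment) != set(self.channel_labels):
            raise ValueError("group_assignment must cover exactly the channel labels")
        groups = set(self.group_assignment.values())
        if groups != {"control", "treated"}:
            raise ValueError(f"need exactly the groups control/treated, got {sorted(groups)}")
        if len(self.control_indices) < 2 or len(self.treated_indices) < 2:
            raise ValueError("each group needs at least 2 channels")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def control_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, c in enumerate(self.channel_labels) if self.group_assignment[c] == "control"
        )

    @property
    def treated_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, c in enumerate(self.channel_labels) if self.group_assignment[c] == "treated"
        )


def default_design() -> TMTDesign:
    return TMTDesign()


@dataclass(frozen=True)
class PeptideQuantRecord:
    """One exported peptide row: annotations plus reporter abundances.

    ``abundances`` is a length-``n_channels`` vector of non-negative
    reporter intensities; missing values are NaN. ``coisolation_percent``
    may be None when the export lacked the column (such rows pass the
    co-isolation filter).
    """

    peptide: str
    accession: str
    mods: tuple[ModAnnotation, ...] = ()
    coisolation_percent: float | None = None
    abundances: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.coisolation_percent is not None and not 0 <= self.coisolation_percent <= 100:
            raise ValueError(
                f"{self.peptide}: co-isolation {self.coisolation_percent} outside [0, 100]"
            )
        arr = np.asarray(self.abundances, dtype=float)
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"{self.peptide}: negative reporter abundance")
        object.__setattr__(self, "abundances", tuple(float(x) for x in arr))

    @property
    def is_quantified(self) -> bool:
        """True iff every channel has a reporter value."""
        return bool(self.abundances) and not np.any(np.isnan(self.abundances))

    def abundance_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=float)


@dataclass(frozen=True)
class QuantResult:
    """Per-peptide inference output."""

    peptide: str
    accession: str
    mods: tuple[ModAnnotation, ...]
    normalized_abundances: tuple[float, ...]
    fold_change: float
    p_value: float
    adj_p_value: float
    category: str
    flags: OxidationClassFlags


@dataclass(frozen=True)
class QuantConfig:
    """Tunable inference parameters.

    alpha: BH-adjusted significance threshold (default 0.05).
    coisolation_threshold: co-isolation interference cutoff in percent;
        peptides above it are discarded (default 30).
    equal_var: pooled-variance Student t when True (default), Welch when
        False.
    """

    alpha: float = 0.05
    coisolation_threshold: float = 30.0
    equal_var: bool = True


@dataclass
class QuantRun:
    """Output of :func:`run_quant`: results plus bookkeeping."""

    results: list[QuantResult]
    detected_only: list[PeptideQuantRecord]
    n_dropped_coisolation: int
    scale_factors: np.ndarray | None
    design: TMTDesign
    config: QuantConfig


def filter_coisolation(
    records: Sequence[PeptideQuantRecord], threshold: float = 30.0
) -> tuple[list[PeptideQuantRecord], int]:
    """Keep records with co-isolation <= ``threshold`` percent (inclusive).

    Records without a co-isolation value are kept. Returns the kept
    records and the number dropped.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    kept = [
        r
        for r in records
        if r.coisolation_percent is None or r.coisolation_percent <= threshold
    ]
    return kept, len(records) - len(kept)


def normalize_channels(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each reporter channel to an equal total signal.

    Each channel (column) is multiplied by mean(column totals) /
    column_total, so all post-normalization totals equal the mean of the
    original totals. Idempotent, and any common target constant would
    yield identical fold changes and p-values.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty abundance matrix")
    totals = np.nansum(matrix, axis=0)
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)
        raise ZeroTotalChannelError(f"channel(s) {bad.tolist()} have zero total signal")
    factors = totals.mean() / totals
    return matrix * factors, factors


def fold_change(row: np.ndarray, design: TMTDesign) -> float:
    """mean(treated channels) / mean(control channels) for one peptide."""
    row = np.asarray(row, dtype=float)
    control = row[list(design.control_indices)]
    treated = row[list(design.treated_indices)]
    control = control[~np.isnan(control)]
    treated = treated[~np.isnan(treated)]
    if control.size == 0 or treated.size == 0:
        raise ValueError("both groups need at least one non-missing value")
    if control.mean() == 0:
        raise UndefinedRatioError("control group mean is zero; fold change undefined")
    return float(treated.mean() / control.mean())


def two_tailed_t_test(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-tailed two-sample t-test p-value.

    Pooled-variance Student form by default (df = nA + nB - 2), Welch
    when ``equal_var=False``. Degenerate inputs where both groups have
    zero variance return p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var() == 0 and b.var() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_i = min over the upper tail of (p_(j) * m / j), clipped at 1;
    output >= input elementwise and preserves the significance order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def categorize_peptide(fold_change: float, adj_p: float, alpha: float = 0.05) -> str:
    """Assign the finest fold-change category.

    Non-significant peptides (adjusted p >= alpha) are ``no_change``.
    Significant increases are ``increase_gt2`` when fold > 2, else
    ``increase_gt1``; significant decreases are ``decrease_lt05`` when
    fold < 0.5, else ``decrease_lt1``. The >2 and <0.5 tiers are subsets
    of >1 and <1 for summary purposes. A significant fold of exactly 1 is
    ``no_change`` (degenerate).
    """
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if adj_p >= alpha or fold_change == 1.0:
        return "no_change"
    if fold_change > 1:
        return "increase_gt2" if fold_change > 2 else "increase_gt1"
    return "decrease_lt05" if fold_change < 0.5 else "decrease_lt1"


def _ttest_pvalues(matrix: np.ndarray, design: TMTDesign, equal_var: bool) -> np.ndarray:
    """Row-wise two-tailed t-test p-values with degenerate conventions."""
    a = matrix[:, list(design.treated_indices)]
    b = matrix[:, list(design.control_indices)]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        equal_means = a.mean(axis=1) == b.mean(axis=1)
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def run_quant(
    records: Sequence[PeptideQuantRecord],
    design: TMTDesign | None = None,
    config: QuantConfig | None = None,
) -> QuantRun:
    """Run the full inference pipeline over exported peptide records.

    Deterministic given its input. Records failing the co-isolation
    filter are dropped; records with any missing reporter channel are
    carried as *detected-only* (they appear in detection summaries but
    receive no statistics). BH adjustment spans all quantified peptides
    as one family.
    """
    design = design or default_design()
    config = config or QuantConfig()

    for rec in records:
        if len(rec.abundances) != design.n_channels:
            raise ValueError(
                f"{rec.peptide}: {len(rec.abundances)} abundances for "
                f"{design.n_channels}-channel design"
            )

    kept, n_dropped = filter_coisolation(records, config.coisolation_threshold)
    quantified = [r for r in kept if r.is_quantified]
    detected_only = [r for r in kept if not r.is_quantified]

    if not quantified:
        return QuantRun([], detected_only, n_dropped, None, design, config)

    matrix = np.vstack([r.abundance_array() for r in quantified])
    normalized, factors = normalize_channels(matrix)

    ci = list(design.control_indices)
    ti = list(design.treated_indices)
    control_means = normalized[:, ci].mean(axis=1)
    treated_means = normalized[:, ti].mean(axis=1)
    if np.any(control_means == 0):
        bad = quantified[int(np.flatnonzero(control_means == 0)[0])]
        raise UndefinedRatioError(f"{bad.peptide}: control group mean is zero")
    folds = treated_means / control_means

    p_values = _ttest_pvalues(normalized, design, config.equal_var)
    adj_p = bh_adjust(p_values)

    results = []
    for rec, row, fc, p, ap in zip(quantified, normalized, folds, p_values, adj_p):
        results.append(
            QuantResult(
                peptide=rec.peptide,
                accession=rec.accession,
                mods=rec.mods,
                normalized_abundances=tuple(float(x) for x in row),
                fold_change=float(fc),
                p_value=float(p),
                adj_p_value=float(ap),
                category=categorize_peptide(float(fc), float(ap), config.alpha),
                flags=classify_oxidative_state(rec.mods),
            )
        )
    return QuantRun(results, detected_only, n_dropped, factors, design, config)
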