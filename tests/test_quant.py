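"""Normalization, t-tests, BH adjustment, categorization and the
composed inference pipeline."""

import numpy as np
import pytest

from oxiprot.quant import (
    PeptideQuantRecord,
    QuantConfig,
    TMTDesign,
    UndefinedRatioError,
    ZeroTotalChannelError,
    bh_adjust,
    categorize_peptide,
    default_design,
    filter_coisolation,
    fold_change,
    normalize_channels,
    run_quant,
    two_tailed_t_test,
)
from oxiprot.synthetic import ACTIVE_SITE_PEPTIDE


def _record(abundances, peptide="PEPTIDEK", coiso=5.0, accession="P1", mods=()):
    return PeptideQuantRecord(
        peptide=peptide,
        accession=accession,
        mods=mods,
        coisolation_percent=coiso,
        abundances=tuple(abundances),
    )


def _bh_oracle(p):
    """Brute-force step-up BH: min over the upper tail of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestDesign:
    def test_default_layout(self):
        d = default_design()
        assert d.n_channels == 10
        assert d.control_indices == (0, 1, 2, 3, 4)
        assert d.treated_indices == (5, 6, 7, 8, 9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            TMTDesign(channel_labels=("a", "b"), group_assignment={"a": "control", "b": "control"})

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            TMTDesign(
                channel_labels=("a", "b", "c"),
                group_assignment={"a": "control", "b": "treated", "c": "treated"},
            )


class TestCoisolationFilter:
    def test_threshold_is_inclusive(self):
        rec = _record([1] * 10, coiso=30.0)
        kept, dropped = filter_coisolation([rec], 30.0)
        assert kept == [rec] and dropped == 0

    def test_just_above_threshold_dropped(self):
        kept, dropped = filter_coisolation([_record([1] * 10, coiso=30.1)], 30.0)
        assert kept == [] and dropped == 1

    def test_missing_coisolation_kept(self):
        rec = _record([1] * 10, coiso=None)
        kept, _ = filter_coisolation([rec], 30.0)
        assert kept == [rec]

    def test_empty_input(self):
        assert filter_coisolation([], 30.0) == ([], 0)


class TestNormalization:
    def test_two_channel_closed_form(self):
        matrix = np.array([[40.0, 120.0], [60.0, 80.0]])  # totals 100, 200
        normalized, factors = normalize_channels(matrix)
        assert factors == pytest.approx([1.5, 0.75])
        assert normalized.sum(axis=0) == pytest.approx([150.0, 150.0])

    def test_equal_totals_identity(self):
        matrix = np.array([[1.0, 2.0], [3.0, 2.0]])
        normalized, factors = normalize_channels(matrix)
        assert factors == pytest.approx([1.0, 1.0])
        assert normalized == pytest.approx(matrix)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        matrix = rng.lognormal(0, 1, size=(50, 10))
        once, _ = normalize_channels(matrix)
        twice, factors2 = normalize_channels(once)
        assert twice == pytest.approx(once, rel=1e-12)
        assert factors2 == pytest.approx(np.ones(10), rel=1e-12)

    def test_equal_total_postcondition(self):
        rng = np.random.default_rng(1)
        matrix = rng.lognormal(0, 1, size=(200, 10)) * rng.uniform(0.5, 2, 10)
        normalized, _ = normalize_channels(matrix)
        totals = normalized.sum(axis=0)
        assert np.allclose(totals, totals[0], rtol=1e-9)

    def test_zero_total_channel_named(self):
        matrix = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ZeroTotalChannelError, match="1"):
            normalize_channels(matrix)


class TestFoldChange:
    def test_doubling(self):
        assert fold_change([1, 1, 1, 1, 1, 2, 2, 2, 2, 2], default_design()) == 2.0

    def test_identity(self):
        assert fold_change([3] * 10, default_design()) == 1.0

    def test_published_magnitude(self):
        row = [10.0] * 5 + [201.2] * 5
        assert fold_change(row, default_design()) == pytest.approx(20.12)

    def test_zero_control_mean_undefined(self):
        with pytest.raises(UndefinedRatioError):
            fold_change([0] * 5 + [1] * 5, default_design())


class TestTTest:
    def test_identical_groups(self):
        assert two_tailed_t_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_textbook_pooled_variance(self):
        # t = -3.6742 on 4 df, two-tailed
        assert two_tailed_t_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.02131, abs=2e-5)

    def test_degenerate_constant_groups(self):
        assert two_tailed_t_test([1, 1], [1, 1]) == 1.0
        assert two_tailed_t_test([1, 1], [2, 2]) == 0.0

    def test_welch_differs_with_unequal_variances(self):
        a, b = [1.0, 1.1, 0.9, 1.0], [2.0, 5.0, -1.0, 3.0]
        student = two_tailed_t_test(a, b, equal_var=True)
        welch = two_tailed_t_test(a, b, equal_var=False)
        assert student != pytest.approx(welch, rel=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_t_test([1], [1, 2])


class TestBHAdjust:
    def test_uniform_ladder(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert adj == pytest.approx([0.05] * 5)

    def test_single_value(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_two_values(self):
        assert bh_adjust([0.02, 0.9]) == pytest.approx([0.04, 0.9])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 21))
            assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 21))
            assert bh_adjust(p) == pytest.approx(_bh_oracle(p), rel=1e-12)


@pytest.mark.parametrize(
    "fold, adj_p, expected",
    [
        (20.12, 0.005, "increase_gt2"),
        (1.5, 0.2, "no_change"),
        (1.5, 0.01, "increase_gt1"),
        (0.4, 0.01, "decrease_lt05"),
        (0.7, 0.01, "decrease_lt1"),
        (0.7, 0.05, "no_change"),  # threshold is strict <
        (1.0, 0.001, "no_change"),  # degenerate exact-1 fold
    ],
)
def test_categorize(fold, adj_p, expected):
    assert categorize_peptide(fold, adj_p) == expected


class TestRunQuant:
    def test_empty_records(self):
        run = run_quant([])
        assert run.results == [] and run.detected_only == []

    def test_missing_channel_routes_to_detected_only(self):
        complete = _record([1.0] * 10, peptide="AAAAK")
        partial = _record([1.0] * 9 + [np.nan], peptide="CCCCK")
        run = run_quant([complete, partial])
        assert [r.peptide for r in run.results] == ["AAAAK"]
        assert [r.peptide for r in run.detected_only] == ["CCCCK"]

    def test_deterministic(self, small_dataset):
        run1 = run_quant(small_dataset["records"])
        run2 = run_quant(small_dataset["records"])
        assert [r.fold_change for r in run1.results] == [r.fold_change for r in run2.results]
        assert [r.category for r in run1.results] == [r.category for r in run2.results]

    def test_planted_large_effect_is_top_and_significant(self, small_dataset):
        run = run_quant(small_dataset["records"])
        top = max(run.results, key=lambda r: r.fold_change)
        assert top.peptide == ACTIVE_SITE_PEPTIDE
        assert top.flags.trioxidized
        assert top.adj_p_value < 0.05
        assert top.fold_change == pytest.approx(20.12, rel=0.10)

    def test_fold_changes_scale_invariant(self, small_dataset):
        records = small_dataset["records"]
        scaled = [
            PeptideQuantRecord(
                peptide=r.peptide,
                accession=r.accession,
                mods=r.mods,
                coisolation_percent=r.coisolation_percent,
                abundances=tuple(np.asarray(r.abundances) * 7.0),
            )
            for r in records
        ]
        run = run_quant(records)
        run_scaled = run_quant(scaled)
        assert [r.fold_change for r in run.results] == pytest.approx(
            [r.fold_change for r in run_scaled.results], rel=1e-12
        )
        assert [r.p_value for r in run.results] == pytest.approx(
            [r.p_value for r in run_scaled.results], rel=1e-9, abs=1e-12
        )

    def test_null_table_mostly_no_change(self):
        rng = np.random.default_rng(9)
        records = [
            _record(rng.lognormal(10, 0.1, 10), peptide=f"PEP{i}K") for i in range(500)
        ]
        run = run_quant(records)
        frac_null = np.mean([r.category == "no_change" for r in run.results])
        assert frac_null >= 0.95

    def test_wrong_vector_length_rejected(self):
        with pytest.raises(ValueError, match="abundances"):
            run_quant([_record([1.0] * 6)])
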