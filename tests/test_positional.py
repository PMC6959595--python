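"""Segment partitioning, informative-position rates, paired tests, hydropathy."""

import math

import numpy as np
import pytest
from scipy import stats

from transub.msa_pipeline import column_mask
from transub.positional import (
    SEGMENT_KINDS,
    column_hydropathy,
    compare_segments,
    informative_rates,
    map_informative_to_sequence,
    paired_t_test,
    partition_positions,
    write_hydropathy_profile,
    write_rate_table,
)
from transub.seqio import Alignment, ColumnMask, TmsAnnotation


def brute_force_partition(seq_len, intervals, margin):
    """Per-position oracle: label each position independently."""
    labels = []
    tms_positions = set()
    interiors = set()
    for start, end in intervals:
        m = end - start + 1
        q = max(1, round(m / 3))
        int_start = start + (m - q) // 2
        for p in range(start, end + 1):
            tms_positions.add(p)
            if int_start <= p < int_start + q:
                interiors.add(p)
    for p in range(1, seq_len + 1):
        if p in tms_positions:
            labels.append("tms_interior" if p in interiors else "tms_exterior")
        elif tms_positions and min(abs(p - t) for t in tms_positions) <= margin:
            labels.append("nontms_close")
        else:
            labels.append("nontms_far")
    return tuple(labels)


class TestPartition:
    def test_worked_example(self):
        part = partition_positions(50, TmsAnnotation("p", ((21, 29),)), margin=10)
        assert set(part.positions("tms_interior")) == {24, 25, 26}
        assert set(part.positions("tms_exterior")) == {21, 22, 23, 27, 28, 29}
        assert set(part.positions("nontms_close")) == set(range(11, 21)) | set(
            range(30, 40)
        )
        assert set(part.positions("nontms_far")) == set(range(1, 11)) | set(
            range(40, 51)
        )

    def test_no_tms_all_far(self):
        part = partition_positions(30, TmsAnnotation("p", ()))
        assert set(part.labels) == {"nontms_far"}

    def test_tms_covering_whole_sequence(self):
        part = partition_positions(9, TmsAnnotation("p", ((1, 9),)))
        assert not part.positions("nontms_close")
        assert not part.positions("nontms_far")

    def test_margin_zero_no_close(self):
        part = partition_positions(50, TmsAnnotation("p", ((21, 29),)), margin=0)
        assert part.positions("nontms_close") == []

    def test_random_layouts_match_brute_force(self, rng):
        for _ in range(100):
            seq_len = int(rng.integers(20, 120))
            n_tms = int(rng.integers(0, 4))
            intervals, cursor = [], 1
            for _ in range(n_tms):
                start = cursor + int(rng.integers(0, 8))
                end = start + int(rng.integers(0, 15))
                if end > seq_len:
                    break
                intervals.append((start, end))
                cursor = end + 2
            margin = int(rng.integers(0, 15))
            ann = TmsAnnotation("p", tuple(intervals))
            part = partition_positions(seq_len, ann, margin=margin)
            assert part.labels == brute_force_partition(seq_len, intervals, margin)
            # coverage: every position labelled exactly once
            assert part.seq_len == seq_len
            assert sum(len(part.positions(k)) for k in SEGMENT_KINDS) == seq_len

    def test_interval_beyond_length_error(self):
        with pytest.raises(ValueError, match="exceeds length"):
            partition_positions(10, TmsAnnotation("p", ((5, 12),)))


class TestMapInformative:
    def test_all_kept(self):
        aln = Alignment(ids=["r"], seqs=["ACDE"])
        mask = ColumnMask(keep=[True] * 4, threshold=0)
        assert map_informative_to_sequence(aln, mask, "r") == {1, 2, 3, 4}

    def test_gap_aware_column_walk(self):
        aln = Alignment(ids=["r", "q"], seqs=["A-CD", "AWCD"])
        mask = ColumnMask(keep=[True, True, False, True], threshold=4)
        # reference ungapped positions: A=col1, C=col3 (dropped), D=col4
        assert map_informative_to_sequence(aln, mask, "r") == {1, 3}

    def test_all_dropped(self):
        aln = Alignment(ids=["r"], seqs=["ACDE"])
        mask = ColumnMask(keep=[False] * 4, threshold=10)
        assert map_informative_to_sequence(aln, mask, "r") == set()

    def test_missing_ref_error(self):
        aln = Alignment(ids=["r"], seqs=["ACDE"])
        mask = ColumnMask(keep=[True] * 4, threshold=0)
        with pytest.raises(KeyError, match="no alignment row"):
            map_informative_to_sequence(aln, mask, "nope")


class TestRates:
    def test_all_informative_rates_100(self):
        part = partition_positions(50, TmsAnnotation("p", ((21, 29),)))
        rec = informative_rates(part, set(range(1, 51)))
        for kind in SEGMENT_KINDS:
            assert rec.rates[kind][2] == 100.0

    def test_empty_segment_flagged_nan(self):
        part = partition_positions(9, TmsAnnotation("p", ((1, 9),)))
        rec = informative_rates(part, {1, 2})
        assert math.isnan(rec.rate("nontms_close"))
        assert math.isnan(rec.rate("nontms_far"))

    def test_hand_tally(self):
        part = partition_positions(10, TmsAnnotation("p", ((4, 6),)), margin=2)
        # interior = {5}; exterior = {4, 6}; close = {2, 3, 7, 8}; far = {1, 9, 10}
        rec = informative_rates(part, {1, 4, 5, 7})
        assert rec.rates["tms_interior"] == (1, 1, 100.0)
        assert rec.rates["tms_exterior"] == (2, 1, 50.0)
        assert rec.rates["nontms_close"] == (4, 1, 25.0)
        assert rec.rates["nontms_far"][0] == 3
        assert rec.rates["nontms_far"][2] == pytest.approx(100 / 3)
        assert rec.rates["tms"] == (3, 2, pytest.approx(200 / 3))

    def test_counts_conserve_informative_total(self, rng):
        part = partition_positions(60, TmsAnnotation("p", ((10, 25), (40, 50))))
        informative = set(rng.choice(60, size=25, replace=False) + 1)
        rec = informative_rates(part, {int(p) for p in informative})
        total = sum(rec.rates[k][1] for k in SEGMENT_KINDS)
        assert total == len(informative)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t_test([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.normal(50, 12, size=n)
            y = x + rng.normal(2, 8, size=n)
            res = paired_t_test(list(x), list(y))
            ref = stats.ttest_rel(x, y)
            assert res.t == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_nan_pairs_dropped(self):
        res = paired_t_test([1.0, math.nan, 5.0, 9.0], [0.0, 3.0, 1.0, 2.0])
        assert res.n == 3

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test([1.0, math.nan], [2.0, 3.0])

    def test_compare_segments(self, rng):
        parts = [
            partition_positions(60, TmsAnnotation(f"p{i}", ((10, 25), (40, 50))))
            for i in range(8)
        ]
        recs = []
        for part in parts:
            # informative positions biased toward the TMS
            inf = {p for p in part.positions("tms") if rng.random() < 0.8}
            inf |= {p for p in part.positions("nontms") if rng.random() < 0.3}
            recs.append(informative_rates(part, inf))
        res = compare_segments(recs, "tms", "nontms")
        assert res.mean_x > res.mean_y
        assert res.p < 0.05


class TestHydropathy:
    def test_all_isoleucine_column(self):
        aln = Alignment(ids=["a", "b"], seqs=["II", "II"])
        prof = column_hydropathy(aln)
        assert prof.mean_hydropathy == (4.5, 4.5)

    def test_all_gap_column_nan(self):
        aln = Alignment(ids=["a", "b"], seqs=["A-", "A-"])
        prof = column_hydropathy(aln)
        assert math.isnan(prof.mean_hydropathy[1])

    def test_mixed_column_mean(self):
        # I (4.5) and R (-4.5) average to 0
        aln = Alignment(ids=["a", "b"], seqs=["I", "R"])
        assert column_hydropathy(aln).mean_hydropathy[0] == pytest.approx(0.0)

    def test_row_order_invariance(self, rng, random_sequence):
        seqs = [random_sequence(30) for _ in range(5)]
        ids = [f"r{i}" for i in range(5)]
        perm = rng.permutation(5)
        a = column_hydropathy(Alignment(ids=ids, seqs=seqs))
        b = column_hydropathy(
            Alignment(ids=[ids[i] for i in perm], seqs=[seqs[i] for i in perm])
        )
        np.testing.assert_allclose(a.mean_hydropathy, b.mean_hydropathy, atol=1e-12)

    def test_carries_reliability_and_mask(self, toy_alignment):
        mask = column_mask(toy_alignment.reliability, 4)
        prof = column_hydropathy(toy_alignment, mask)
        assert prof.reliability == tuple(toy_alignment.reliability)
        assert prof.kept == tuple(mask.keep)

    def test_exports(self, tmp_path, toy_alignment):
        mask = column_mask(toy_alignment.reliability, 4)
        prof = column_hydropathy(toy_alignment, mask)
        f = tmp_path / "prof.tsv"
        write_hydropathy_profile(prof, f)
        lines = f.read_text().splitlines()
        assert lines[0] == "column\tmean_hydropathy\treliability\tkept"
        assert len(lines) == toy_alignment.n_cols + 1
        part = partition_positions(7, TmsAnnotation("s1", ((2, 5),)))
        rec = informative_rates(part, {1, 2, 3})
        write_rate_table([rec], tmp_path / "rates.tsv")
        assert "seq_id" in (tmp_path / "rates.tsv").read_text()
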