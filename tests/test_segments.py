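from fractions import Fraction

import numpy as np
import pytest

from cncohort.io import CopyNumberSegment, PloidyTable, SegmentSet
from cncohort.segments import (
    build_segment_matrix,
    classify_cells,
    classify_one,
    export_segment_matrix,
)

from conftest import random_cohort


def seg(sample, chrom, start, end, maj, mino):
    return CopyNumberSegment(sample, chrom, start, end, maj, mino)


class TestPartition:
    def test_two_sample_breakpoint_intersection(self):
        ss = SegmentSet.from_iterable(
            [seg("A", "c1", 100, 200, 2, 1), seg("B", "c1", 150, 250, 1, 0)]
        )
        ms = build_segment_matrix(ss, coalesce=False)
        assert ms.intervals == (
            ("c1", 100, 150), ("c1", 150, 200), ("c1", 200, 250),
        )
        assert ms.cells[(0, "A")].total == 3
        assert ms.cells[(1, "A")].total == 3
        assert ms.cells[(1, "B")].total == 1
        assert ms.cells[(2, "B")].total == 1
        assert (0, "B") not in ms.cells and (2, "A") not in ms.cells

    def test_single_call_is_identity(self):
        ss = SegmentSet.from_iterable([seg("A", "c1", 10, 99, 2, 2)])
        ms = build_segment_matrix(ss)
        assert ms.intervals == (("c1", 10, 99),)
        assert ms.cells[(0, "A")] == (2, 2)

    def test_idempotent_on_partitioned_input(self):
        ss = SegmentSet.from_iterable(
            [seg("A", "c1", 0, 50, 2, 1), seg("B", "c1", 0, 50, 3, 0),
             seg("A", "c1", 50, 90, 1, 0)]
        )
        ms1 = build_segment_matrix(ss, coalesce=False)
        rebuilt = SegmentSet.from_iterable(
            [
                seg(s, c[0], c[1], c[2], cell.n_major, cell.n_minor)
                for (i, s), cell in ms1.cells.items()
                for c in [ms1.intervals[i]]
            ]
        )
        ms2 = build_segment_matrix(rebuilt, coalesce=False)
        assert ms1.intervals == ms2.intervals
        assert dict(ms1.cells) == dict(ms2.cells)

    @pytest.mark.parametrize("seed", range(10))
    def test_perbase_oracle(self, small_build, seed):
        ss = random_cohort(np.random.default_rng(seed), small_build)
        ms = build_segment_matrix(ss)
        for sample in ss.samples:
            for chrom, length in small_build.chromosomes:
                want = np.full(length, -1, dtype=np.int64)
                for c in ss.of(sample, chrom):
                    want[c.start : c.end] = c.total_cn
                got = np.full(length, -1, dtype=np.int64)
                for i, (ch, s, e) in enumerate(ms.intervals):
                    if ch != chrom:
                        continue
                    cell = ms.cells.get((i, sample))
                    if cell is not None:
                        got[s:e] = cell.total
                assert (want == got).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_covered_length_conserved(self, small_build, seed):
        ss = random_cohort(np.random.default_rng(seed + 50), small_build)
        ms = build_segment_matrix(ss)
        for sample in ss.samples:
            assert ms.covered_length(sample) == ss.covered_length(sample)

    def test_fragmentation_invariance(self):
        whole = SegmentSet.from_iterable(
            [seg("A", "c1", 0, 1000, 3, 1), seg("B", "c1", 200, 600, 2, 0)]
        )
        split = SegmentSet.from_iterable(
            [
                seg("A", "c1", 0, 137, 3, 1), seg("A", "c1", 137, 611, 3, 1),
                seg("A", "c1", 611, 1000, 3, 1), seg("B", "c1", 200, 600, 2, 0),
            ]
        )
        pt = PloidyTable({"A": 2, "B": 2})
        a = classify_cells(build_segment_matrix(whole), pt)
        b = classify_cells(build_segment_matrix(split), pt)
        assert a.intervals == b.intervals  # coalescing removes the splits
        assert dict(a.cells) == dict(b.cells)
        assert dict(a.events) == dict(b.events)

    def test_coalesce_merges_identical_neighbours(self):
        ss = SegmentSet.from_iterable(
            [seg("A", "c1", 0, 50, 2, 1), seg("A", "c1", 50, 100, 2, 1)]
        )
        ms = build_segment_matrix(ss)
        assert ms.intervals == (("c1", 0, 100),)


class TestClassification:
    def test_cn_loh_neutral_homozygous(self):
        ev = classify_one(2, 0, 2)
        assert ev.is_cn_loh and ev.is_loh and ev.is_homozygous
        assert not ev.is_heterozygous and ev.state == "neutral"
        assert ev.category == 0

    def test_loh_loss_is_not_cn_loh(self):
        ev = classify_one(1, 0, 2)
        assert ev.is_loh and not ev.is_cn_loh
        assert ev.is_homozygous and ev.state == "loss"

    def test_heterozygous_gain(self):
        ev = classify_one(2, 1, 2)
        assert ev.is_heterozygous and not ev.is_loh and ev.state == "gain"

    def test_total_deletion_is_not_loh(self):
        ev = classify_one(0, 0, 2)
        assert ev.is_homozygous and ev.state == "loss" and not ev.is_loh

    def test_category_clamped(self):
        assert classify_one(10, 4, 2).category == 6
        assert classify_one(0, 0, 6).category == -4

    def test_fractional_ploidy_uses_rounded(self):
        # ploidy 2.5 rounds to 3: cn-LOH needs (3, 0); neutral needs total 3
        ev = classify_one(3, 0, Fraction(5, 2))
        assert ev.is_cn_loh and ev.state == "neutral"
        assert classify_one(2, 0, Fraction(5, 2)).state == "loss"

    def test_truth_table_over_small_states(self):
        # re-derive every flag from the definitions, independently
        for p in range(1, 7):
            for maj in range(0, 7):
                for mino in range(0, maj + 1):
                    ev = classify_one(maj, mino, p)
                    total = maj + mino
                    assert ev.is_loh == (mino == 0 and maj >= 1)
                    assert ev.is_cn_loh == (mino == 0 and maj == p)
                    assert ev.is_homozygous == (min(maj, mino) == 0)
                    assert ev.is_heterozygous == (min(maj, mino) > 0)
                    assert ev.state == (
                        "gain" if total > p else "loss" if total < p else "neutral"
                    )
                    assert ev.category == max(-4, min(6, total - p))
                    # structural invariants
                    assert not ev.is_cn_loh or ev.is_loh
                    assert ev.is_homozygous != ev.is_heterozygous

    def test_missing_ploidy_rejected(self):
        ss = SegmentSet.from_iterable([seg("A", "c1", 0, 10, 2, 1)])
        ms = build_segment_matrix(ss)
        with pytest.raises(KeyError):
            classify_cells(ms, PloidyTable({"B": 2}))


def test_export_contains_flags(tmp_path):
    ss = SegmentSet.from_iterable(
        [seg("A", "c1", 0, 100, 2, 0), seg("B", "c1", 0, 100, 2, 1)]
    )
    ms = classify_cells(build_segment_matrix(ss), PloidyTable({"A": 2, "B": 2}))
    path = export_segment_matrix(ms, str(tmp_path / "ms.tsv"))
    lines = open(path).read().splitlines()
    assert lines[0].split("\t")[-6:] == [
        "category", "state", "cn_loh", "loh", "homozygous", "heterozygous",
    ]
    row_a = next(l for l in lines if "\tA\t" in l)
    assert row_a.split("\t")[8:10] == ["neutral", "1"]
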