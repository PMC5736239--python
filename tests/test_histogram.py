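import numpy as np
import pytest

from cncohort.genome import GenomeBuild, make_windows
from cncohort.histogram import (
    compute_hethom_frequencies,
    compute_loh_tracks,
    compute_stacked_frequencies,
    display_bin,
    export_event_text,
    export_loh_tracks,
    parse_event_text,
)
from cncohort.io import CopyNumberSegment, PloidyTable, SegmentSet
from cncohort.matrix import build_matrix, to_relative
from cncohort.segments import build_segment_matrix, classify_cells


def seg(sample, chrom, start, end, maj, mino):
    return CopyNumberSegment(sample, chrom, start, end, maj, mino)


@pytest.fixture
def four_sample_ms():
    # one shared interval with relative values {+1, +1, -1, 0} at ploidy 2
    ss = SegmentSet.from_iterable(
        [
            seg("S1", "c1", 0, 100, 2, 1),
            seg("S2", "c1", 0, 100, 3, 0),
            seg("S3", "c1", 0, 100, 1, 0),
            seg("S4", "c1", 0, 100, 1, 1),
        ]
    )
    pt = PloidyTable({s: 2 for s in ("S1", "S2", "S3", "S4")})
    return classify_cells(build_segment_matrix(ss), pt), pt


class TestStackedFrequencies:
    def test_counting(self, four_sample_ms):
        ms, _ = four_sample_ms
        h = compute_stacked_frequencies(ms)
        assert h.percentage(0, 1) == 50.0
        assert h.percentage(0, -1) == 25.0
        assert h.percentage(0, 0) == 25.0
        assert h.samples_in(0, 1) == ("S1", "S2")

    def test_absent_samples_count_nowhere(self):
        ss = SegmentSet.from_iterable(
            [seg("A", "c1", 0, 100, 1, 1), seg("B", "c1", 50, 150, 3, 1)]
        )
        pt = PloidyTable({"A": 2, "B": 2})
        h = compute_stacked_frequencies(classify_cells(build_segment_matrix(ss), pt))
        # piece [0,50): only A (neutral); B is absent, not neutral
        i = h.overlapping("c1", 0, 50)[0]
        assert h.samples_in(i, 0) == ("A",)
        assert sum(len(h.samples_in(i, c)) for c in h.categories) == 1

    def test_single_neutral_sample(self):
        ss = SegmentSet.from_iterable([seg("A", "c1", 0, 100, 1, 1)])
        pt = PloidyTable({"A": 2})
        h = compute_stacked_frequencies(classify_cells(build_segment_matrix(ss), pt))
        for cat in h.categories:
            if cat != 0:
                assert h.track(cat).sum() == 0.0

    def test_windowed_variant_requires_relative(self, small_build):
        ws = make_windows(small_build, size=100_000)
        ss = SegmentSet.from_iterable([seg("A", "c1", 0, 1_000_000, 1, 1)])
        pt = PloidyTable({"A": 2})
        m = build_matrix(ss, ws, ploidies=pt)
        with pytest.raises(ValueError, match="relative"):
            compute_stacked_frequencies(m)
        h = compute_stacked_frequencies(to_relative(m, pt))
        assert h.n_cohort == 1
        assert len(h.intervals) == len(ws)

    def test_full_and_windowed_agree_on_window_aligned_events(self):
        b = GenomeBuild("t", (("c1", 1_000_000),))
        ws = make_windows(b, size=100_000)
        samples = [f"S{i}" for i in range(1, 5)]
        segs = []
        for s in samples:
            # +2 gain on windows 2..4 for S1, S2; diploid elsewhere
            if s in ("S1", "S2"):
                segs += [
                    seg(s, "c1", 0, 200_000, 1, 1),
                    seg(s, "c1", 200_000, 500_000, 3, 1),
                    seg(s, "c1", 500_000, 1_000_000, 1, 1),
                ]
            else:
                segs.append(seg(s, "c1", 0, 1_000_000, 1, 1))
        ss = SegmentSet.from_iterable(segs)
        pt = PloidyTable({s: 2 for s in samples})
        hf = compute_stacked_frequencies(classify_cells(build_segment_matrix(ss), pt))
        hw = compute_stacked_frequencies(to_relative(build_matrix(ss, ws, ploidies=pt), pt))
        for wi, w in enumerate(ws):
            fi = [i for i in hf.overlapping("c1", w.start, w.end)]
            for cat in range(-4, 7):
                got = {hf.percentage(i, cat) for i in fi}
                assert got == {hw.percentage(wi, cat)}


class TestLohTracks:
    def test_cn_loh_percentage_negative(self):
        segs = [seg(f"S{i}", "c1", 0, 100, 2, 0) for i in (1, 2)]
        segs += [seg(f"S{i}", "c1", 0, 100, 1, 1) for i in range(3, 9)]
        pt = PloidyTable({f"S{i}": 2 for i in range(1, 9)})
        ms = classify_cells(build_segment_matrix(SegmentSet.from_iterable(segs)), pt)
        tracks = compute_loh_tracks(ms, mode="cn-LOH")
        assert tracks["cn-LOH"].values[0] == -25.0

    def test_mode_none_is_empty(self, four_sample_ms):
        ms, _ = four_sample_ms
        assert compute_loh_tracks(ms, mode="none") == {}

    def test_invalid_mode_rejected(self, four_sample_ms):
        ms, _ = four_sample_ms
        with pytest.raises(ValueError, match="mode"):
            compute_loh_tracks(ms, mode="blue")

    def test_loss_loh_counts_only_in_loh_line(self):
        segs = [
            seg("S1", "c1", 0, 100, 1, 0),  # (1,0): LOH loss, not cn-LOH
            seg("S2", "c1", 0, 100, 1, 1),
        ]
        pt = PloidyTable({"S1": 2, "S2": 2})
        ms = classify_cells(build_segment_matrix(SegmentSet.from_iterable(segs)), pt)
        tracks = compute_loh_tracks(ms, mode="both")
        assert tracks["LOH"].values[0] == -50.0
        assert tracks["cn-LOH"].values[0] == 0.0


class TestHetHom:
    def test_classes(self):
        segs = [
            seg("S1", "c1", 0, 100, 2, 0),  # hom-neutral
            seg("S2", "c1", 0, 100, 2, 2),  # het-gain
            seg("S3", "c1", 0, 100, 1, 1),  # het-neutral
        ]
        pt = PloidyTable({"S1": 2, "S2": 2, "S3": 2})
        h = compute_hethom_frequencies(
            classify_cells(build_segment_matrix(SegmentSet.from_iterable(segs)), pt)
        )
        assert h.samples_in(0, "hom-neutral") == ("S1",)
        assert h.samples_in(0, "het-gain") == ("S2",)
        assert h.samples_in(0, "het-neutral") == ("S3",)

    def test_all_het_neutral_100pct(self):
        segs = [seg(f"S{i}", "c1", 0, 100, 1, 1) for i in range(1, 6)]
        pt = PloidyTable({f"S{i}": 2 for i in range(1, 6)})
        h = compute_hethom_frequencies(
            classify_cells(build_segment_matrix(SegmentSet.from_iterable(segs)), pt)
        )
        assert h.percentage(0, "het-neutral") == 100.0


class TestExport:
    def test_round_trip(self, tmp_path, four_sample_ms):
        ms, _ = four_sample_ms
        h = compute_stacked_frequencies(ms)
        path = export_event_text(h, str(tmp_path / "ev.tsv"))
        back = parse_event_text(path, h.n_cohort)
        assert back.intervals == h.intervals
        for i in range(len(h.intervals)):
            for cat in h.categories:
                assert back.percentage(i, cat) == h.percentage(i, cat)

    def test_sample_list_serialization(self, tmp_path, four_sample_ms):
        ms, _ = four_sample_ms
        h = compute_stacked_frequencies(ms)
        path = export_event_text(h, str(tmp_path / "ev.tsv"))
        lines = open(path).read().splitlines()
        plus1 = next(l for l in lines if "\t+1\t" in l)
        assert plus1.endswith("S1,S2")
        # empty categories are omitted
        assert not any("\t+3\t" in l for l in lines)

    def test_loh_track_export(self, tmp_path, four_sample_ms):
        ms, _ = four_sample_ms
        tracks = compute_loh_tracks(ms, mode="both")
        path = export_loh_tracks(tracks, str(tmp_path / "loh.tsv"))
        lines = open(path).read().splitlines()
        assert lines[0].startswith("chrom")
        assert any("\tLOH\t" in l for l in lines)


def test_display_bin_pools_high_gains():
    assert display_bin(3) == "+3"
    assert display_bin(4) == ">=+4"
    assert display_bin(6) == ">=+4"
    assert display_bin(-2) == "-2"
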