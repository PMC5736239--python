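"""Cohort-wide stacked frequency tracks.

For every interval of the base-resolution partition (or every window, when
full resolution is disabled) and every relative copy-number category in
[-4, +6], the percentage of the whole cohort carrying that category is
computed together with the explicit sample list.  Companion tracks report
cn-LOH / LOH percentages (drawn as lines in negative ordinates) and the
six heterozygous/homozygous x gain/neutral/loss classes.

The denominator is always the full cohort size N; samples without a call
on an interval count in no category.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import chrom_sort_key
from .io import PloidyTable
from .matrix import CNVMatrix, RELATIVE_MAX, RELATIVE_MIN
from .segments import SegmentMatrix, classify_cells

CNV_CATEGORIES = tuple(range(RELATIVE_MIN, RELATIVE_MAX + 1))  # -4 .. +6
HETHOM_CATEGORIES = (
    "het-gain",
    "het-neutral",
    "het-loss",
    "hom-gain",
    "hom-neutral",
    "hom-loss",
)
LOH_MODES = ("cn-LOH", "LOH", "both", "none")

# display binning: gains at or above this relative value are pooled ("≥ +4")
DISPLAY_TOP_BIN = 4


@dataclass(frozen=True)
class HistogramTable:
    """Per-interval stacked percentages with explicit sample lists."""

    intervals: tuple[tuple[str, int, int], ...]
    n_cohort: int
    categories: tuple
    members: Mapping[tuple[int, object], tuple[str, ...]]  # (interval, cat) -> samples

    def samples_in(self, interval_idx: int, category) -> tuple[str, ...]:
        return self.members.get((interval_idx, category), ())

    def percentage(self, interval_idx: int, category) -> float:
        return 100.0 * len(self.samples_in(interval_idx, category)) / self.n_cohort

    def track(self, category) -> np.ndarray:
        """Percentage of the cohort in ``category`` across all intervals."""
        return np.array(
            [self.percentage(i, category) for i in range(len(self.intervals))]
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        return [
            i
            for i, (c, s, e) in enumerate(self.intervals)
            if c == chrom and s < end and e > start
        ]


@dataclass(frozen=True)
class LineTrack:
    """A percentage line over the partition, in negative ordinates."""

    kind: str  # "cn-LOH" | "LOH"
    intervals: tuple[tuple[str, int, int], ...]
    values: tuple[float, ...]  # negative percentages
    members: tuple[tuple[str, ...], ...]


def _require_classified(ms: SegmentMatrix, ploidies: PloidyTable | None) -> SegmentMatrix:
    if ms.events is None:
        if ploidies is None:
            raise ValueError("segment matrix is unclassified and no ploidies given")
        return classify_cells(ms, ploidies)
    return ms


def compute_stacked_frequencies(
    source: SegmentMatrix | CNVMatrix,
    ploidies: PloidyTable | None = None,
) -> HistogramTable:
    """Stacked CNV-category frequencies.

    ``source`` is either a (classified) :class:`SegmentMatrix` — the
    full-resolution default — or a *relative* :class:`CNVMatrix` for the
    windowed variant.
    """
    if isinstance(source, CNVMatrix):
        if source.flavor != "relative":
            raise ValueError("windowed histogram needs a relative matrix")
        intervals = tuple((w.chrom, w.start, w.end) for w in source.windows)
        members: dict[tuple[int, object], tuple[str, ...]] = {}
        for wi in range(len(source.windows)):
            col = source.values[:, wi]
            for cat in CNV_CATEGORIES:
                hit = tuple(
                    s for s, v in zip(source.samples, col) if int(v) == cat
                )
                if hit:
                    members[(wi, cat)] = hit
        return HistogramTable(
            intervals=intervals,
            n_cohort=len(source.samples),
            categories=CNV_CATEGORIES,
            members=members,
        )
    ms = _require_classified(source, ploidies)
    if len(ms.samples) == 0:
        raise ValueError("empty cohort")
    members = {}
    acc: dict[tuple[int, int], list[str]] = {}
    for (i, sample), ev in ms.events.items():
        acc.setdefault((i, ev.category), []).append(sample)
    for key, samples in acc.items():
        members[key] = tuple(sorted(samples))
    return HistogramTable(
        intervals=ms.intervals,
        n_cohort=len(ms.samples),
        categories=CNV_CATEGORIES,
        members=members,
    )


def compute_loh_tracks(
    ms: SegmentMatrix,
    mode: str = "cn-LOH",
    ploidies: PloidyTable | None = None,
) -> dict[str, LineTrack]:
    """cn-LOH (black line) and/or LOH (blue line) percentage tracks,
    reported in negative ordinates."""
    if mode not in LOH_MODES:
        raise ValueError(f"mode must be one of {LOH_MODES}, got {mode!r}")
    if mode == "none":
        return {}
    ms = _require_classified(ms, ploidies)
    n = len(ms.samples)
    kinds = {"cn-LOH": ["cn-LOH"], "LOH": ["LOH"], "both": ["cn-LOH", "LOH"]}[mode]
    out = {}
    for kind in kinds:
        flag = "is_cn_loh" if kind == "cn-LOH" else "is_loh"
        values, lists = [], []
        for i in range(len(ms.intervals)):
            hit = tuple(
                sorted(
                    s
                    for s in ms.samples_at(i)
                    if getattr(ms.events[(i, s)], flag)
                )
            )
            lists.append(hit)
            values.append(-100.0 * len(hit) / n)
        out[kind] = LineTrack(
            kind=kind,
            intervals=ms.intervals,
            values=tuple(values),
            members=tuple(lists),
        )
    return out


def compute_hethom_frequencies(
    ms: SegmentMatrix, ploidies: PloidyTable | None = None
) -> HistogramTable:
    """Six stacked classes: {het, hom} x {gain, neutral, loss}.

    Percentages are stored positive; the loss classes are drawn in
    negative ordinates by the renderer.
    """
    ms = _require_classified(ms, ploidies)
    if len(ms.samples) == 0:
        raise ValueError("empty cohort")
    acc: dict[tuple[int, str], list[str]] = {}
    for (i, sample), ev in ms.events.items():
        zyg = "het" if ev.is_heterozygous else "hom"
        acc.setdefault((i, f"{zyg}-{ev.state}"), []).append(sample)
    members = {key: tuple(sorted(v)) for key, v in acc.items()}
    return HistogramTable(
        intervals=ms.intervals,
        n_cohort=len(ms.samples),
        categories=HETHOM_CATEGORIES,
        members=members,
    )


def _fmt_category(cat) -> str:
    return f"{cat:+d}" if isinstance(cat, (int, np.integer)) else str(cat)


def export_event_text(h: HistogramTable, out: str) -> str:
    """Tab-delimited export: chrom, start, end, category, percentage,
    comma-joined sample list; empty categories omitted."""
    with open(out, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tpercentage\tsamples\n")
        for i, (chrom, s, e) in enumerate(h.intervals):
            for cat in h.categories:
                samples = h.samples_in(i, cat)
                if not samples:
                    continue
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{_fmt_category(cat)}\t"
                    f"{h.percentage(i, cat):.6f}\t{','.join(samples)}\n"
                )
    return out


def parse_event_text(path: str, n_cohort: int) -> HistogramTable:
    """Round-trip reader for :func:`export_event_text`."""
    intervals: list[tuple[str, int, int]] = []
    members: dict[tuple[int, object], tuple[str, ...]] = {}
    cats: list = []
    index: dict[tuple[str, int, int], int] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            chrom, s, e, cat, _, samples = line.rstrip("\n").split("\t")
            iv = (chrom, int(s), int(e))
            if iv not in index:
                index[iv] = len(intervals)
                intervals.append(iv)
            try:
                cat_key: object = int(cat)
            except ValueError:
                cat_key = cat
            if cat_key not in cats:
                cats.append(cat_key)
            members[(index[iv], cat_key)] = tuple(samples.split(","))
    return HistogramTable(
        intervals=tuple(intervals),
        n_cohort=n_cohort,
        categories=tuple(cats),
        members=members,
    )


def export_loh_tracks(tracks: Mapping[str, LineTrack], out: str) -> str:
    with open(out, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tpercentage\tsamples\n")
        for kind in sorted(tracks):
            tr = tracks[kind]
            for (chrom, s, e), val, samples in zip(
                tr.intervals, tr.values, tr.members
            ):
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{kind}\t{val:.6f}\t{','.join(samples)}\n"
                )
    return out


def display_bin(category: int, top: int = DISPLAY_TOP_BIN) -> str:
    """Display label for a relative category; gains >= ``top`` are pooled."""
    if category >= top:
        return f">=+{top}"
    return f"{category:+d}"
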