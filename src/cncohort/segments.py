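"""Base-resolution segment matrix and per-cell event classification.

The genome is partitioned at the union of all samples' breakpoints, so
that the resulting intervals are non-overlapping and each input call maps
onto the pieces it covers without inventing values for uncovered samples
("absent" cells stay absent).  This is the full-resolution counterpart of
the windowed matrix: no averaging, no fill.

Classification of a cell with allele copies (n_major, n_minor) against the
sample ploidy p (rounded to the nearest integer rp when fractional):

* cn-LOH  — n_minor = 0 and n_major = rp (one allele lost, total unchanged)
* LOH     — n_minor = 0 and n_major >= 1 (all copies of one allele lost);
  a homozygous total deletion (0, 0) is *not* counted as LOH since no
  allele is retained
* homozygous / heterozygous — min(n_major, n_minor) = 0 / both > 0
* gain / neutral / loss — sign of total - rp
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

from ._util import round_half_away
from .genome import chrom_sort_key
from .io import PloidyTable, SegmentSet
from .matrix import RELATIVE_MAX, RELATIVE_MIN


class Cell(NamedTuple):
    n_major: int
    n_minor: int

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class EventCell:
    """Classification of one (sample, segment) cell."""

    category: int  # relative copy number, clamped to [-4, +6]
    state: str  # "gain" | "neutral" | "loss"
    is_cn_loh: bool
    is_loh: bool
    is_homozygous: bool
    is_heterozygous: bool


def classify_one(n_major: int, n_minor: int, ploidy) -> EventCell:
    """Classify a single allele-specific copy-number state."""
    rp = round_half_away(ploidy)
    total = n_major + n_minor
    category = max(RELATIVE_MIN, min(RELATIVE_MAX, total - rp))
    state = "gain" if total > rp else ("loss" if total < rp else "neutral")
    is_loh = n_minor == 0 and n_major >= 1
    return EventCell(
        category=category,
        state=state,
        is_cn_loh=is_loh and n_major == rp,
        is_loh=is_loh,
        is_homozygous=min(n_major, n_minor) == 0,
        is_heterozygous=min(n_major, n_minor) > 0,
    )


@dataclass(frozen=True)
class SegmentMatrix:
    """Breakpoint-partitioned intervals x samples.

    ``cells`` maps (interval index, sample) to a :class:`Cell`; samples with
    no call on an interval simply have no entry.  ``events`` is populated by
    :func:`classify_cells`.
    """

    intervals: tuple[tuple[str, int, int], ...]  # (chrom, start, end), sorted
    samples: tuple[str, ...]
    cells: Mapping[tuple[int, str], Cell]
    events: Mapping[tuple[int, str], EventCell] | None = None

    def __len__(self):
        return len(self.intervals)

    def interval_length(self, idx: int) -> int:
        _, s, e = self.intervals[idx]
        return e - s

    def samples_at(self, idx: int) -> list[str]:
        return [s for s in self.samples if (idx, s) in self.cells]

    def covered_length(self, sample: str) -> int:
        return sum(
            self.interval_length(i)
            for i in range(len(self.intervals))
            if (i, sample) in self.cells
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Indices of partition intervals intersecting [start, end)."""
        return [
            i
            for i, (c, s, e) in enumerate(self.intervals)
            if c == chrom and s < end and e > start
        ]


def _coalesce(
    intervals: list[tuple[str, int, int]],
    cells: dict[tuple[int, str], Cell],
) -> tuple[list[tuple[str, int, int]], dict[tuple[int, str], Cell]]:
    """Merge adjacent contiguous intervals whose sample->cell maps are
    identical (frequency-preserving compaction)."""
    out_iv: list[tuple[str, int, int]] = []
    out_cells: dict[tuple[int, str], Cell] = {}
    col_of: dict[int, dict[str, Cell]] = {i: {} for i in range(len(intervals))}
    for (i, sample), cell in cells.items():
        col_of[i][sample] = cell
    last_col: dict[str, Cell] = {}
    for i, (chrom, s, e) in enumerate(intervals):
        if out_iv:
            pc, ps, pe = out_iv[-1]
            if pc == chrom and pe == s and last_col == col_of[i]:
                out_iv[-1] = (pc, ps, e)
                continue
        j = len(out_iv)
        out_iv.append((chrom, s, e))
        last_col = col_of[i]
        for sample, cell in last_col.items():
            out_cells[(j, sample)] = cell
    return out_iv, out_cells


def build_segment_matrix(segs: SegmentSet, coalesce: bool = True) -> SegmentMatrix:
    """Partition the cohort's calls at all breakpoints.

    The partition's union equals the union of the input call intervals;
    each call contributes its copy numbers to every piece it covers.
    """
    samples = segs.samples
    intervals: list[tuple[str, int, int]] = []
    cells: dict[tuple[int, str], Cell] = {}
    for chrom in segs.chroms:
        calls = [s for s in segs if s.chrom == chrom]
        bounds = sorted({p for c in calls for p in (c.start, c.end)})
        pieces = [
            (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
        ]
        base = len(intervals)
        piece_used = [False] * len(pieces)
        # map each call onto the pieces it covers
        import bisect

        starts = [p[0] for p in pieces]
        for call in calls:
            lo = bisect.bisect_left(starts, call.start)
            for k in range(lo, len(pieces)):
                ps, pe = pieces[k]
                if ps >= call.end:
                    break
                piece_used[k] = True
        keep = [k for k, used in enumerate(piece_used) if used]
        remap = {k: base + i for i, k in enumerate(keep)}
        for k in keep:
            intervals.append((chrom, pieces[k][0], pieces[k][1]))
        for call in calls:
            lo = bisect.bisect_left(starts, call.start)
            for k in range(lo, len(pieces)):
                ps, pe = pieces[k]
                if ps >= call.end:
                    break
                cells[(remap[k], call.sample)] = Cell(call.n_major, call.n_minor)
    if coalesce:
        intervals, cells = _coalesce(intervals, cells)
    return SegmentMatrix(
        intervals=tuple(intervals), samples=tuple(samples), cells=cells
    )


def classify_cells(ms: SegmentMatrix, ploidies: PloidyTable) -> SegmentMatrix:
    """Return a copy of ``ms`` with every cell classified against its
    sample's ploidy."""
    missing = [s for s in ms.samples if s not in ploidies]
    if missing:
        raise KeyError(f"samples missing from ploidy table: {missing}")
    rounded = {s: round_half_away(ploidies[s]) for s in ms.samples}
    events = {
        key: classify_one(cell.n_major, cell.n_minor, rounded[key[1]])
        for key, cell in ms.cells.items()
    }
    return replace(ms, events=events)


def export_segment_matrix(ms: SegmentMatrix, path: str) -> str:
    """Tab-delimited export: one row per (interval, sample) cell with copy
    numbers and, when classified, the event flags."""
    classified = ms.events is not None
    with open(path, "w") as fh:
        header = "chrom\tstart\tend\tsample\tn_major\tn_minor\ttotal_cn"
        if classified:
            header += "\tcategory\tstate\tcn_loh\tloh\thomozygous\theterozygous"
        fh.write(header + "\n")
        for i, (chrom, s, e) in enumerate(ms.intervals):
            for sample in ms.samples:
                cell = ms.cells.get((i, sample))
                if cell is None:
                    continue
                row = (
                    f"{chrom}\t{s}\t{e}\t{sample}\t{cell.n_major}\t"
                    f"{cell.n_minor}\t{cell.total}"
                )
                if classified:
                    ev = ms.events[(i, sample)]
                    row += (
                        f"\t{ev.category:+d}\t{ev.state}\t{int(ev.is_cn_loh)}\t"
                        f"{int(ev.is_loh)}\t{int(ev.is_homozygous)}\t"
                        f"{int(ev.is_heterozygous)}"
                    )
                fh.write(row + "\n")
    return path
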