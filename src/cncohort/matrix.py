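"""Windowed copy-number matrices.

:func:`build_matrix` turns a set of per-sample segment calls into a dense
samples x windows matrix of integer copy numbers: inside each window, every
base carries either its called total copy number or a fill value (the
sample's ploidy for the analysis matrix, a fixed 2 for the ploidy-estimation
matrix), and the entry is the length-weighted mean rounded half away from
zero.  The arithmetic is exact (integer/rational), so a mean landing exactly
on .5 rounds deterministically.

:func:`to_relative` recentres an absolute matrix on each sample's ploidy
(0 = no net change) and clamps to [-4, +6] for display and clustering.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np

from ._util import as_fraction, round_half_away, round_ratio_half_away
from .genome import WindowSet
from .io import PloidyTable, SegmentSet

RELATIVE_MIN = -4
RELATIVE_MAX = 6


@dataclass(frozen=True)
class CNVMatrix:
    """Samples x windows integer copy numbers (absolute or relative)."""

    samples: tuple[str, ...]
    windows: WindowSet
    values: np.ndarray  # shape (n_samples, n_windows), int
    flavor: str  # "absolute" | "relative"

    def __post_init__(self):
        if self.values.shape != (len(self.samples), len(self.windows)):
            raise ValueError("matrix shape does not match samples x windows")
        if self.flavor not in ("absolute", "relative"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "absolute" and (self.values < 0).any():
            raise ValueError("absolute matrix must be non-negative")

    def row(self, sample: str) -> np.ndarray:
        return self.values[self.samples.index(sample)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.samples), columns=self.windows.labels
        )


def build_matrix(
    segs: SegmentSet,
    windows: WindowSet,
    ploidies: PloidyTable | None = None,
    fill_value: int | None = None,
) -> CNVMatrix:
    """Build the absolute windowed matrix.

    Uncovered bases of a window are filled with ``fill_value`` when given
    (the ploidy-estimation matrix uses 2), otherwise with the sample's
    ploidy from ``ploidies``.
    """
    if fill_value is None and ploidies is None:
        raise ValueError("need either a fill_value or a ploidy table")
    samples = segs.samples
    if fill_value is None:
        missing = [s for s in samples if s not in ploidies]
        if missing:
            raise KeyError(f"samples missing from ploidy table: {missing}")
    n_win = len(windows)
    values = np.zeros((len(samples), n_win), dtype=np.int64)

    win_len = np.array([w.length for w in windows], dtype=np.int64)
    for si, sample in enumerate(samples):
        called_sum = np.zeros(n_win, dtype=object)  # exact big-int sums
        called_len = np.zeros(n_win, dtype=np.int64)
        for chrom in segs.chroms:
            for seg in segs.of(sample, chrom):
                for w in windows.overlapping(chrom, seg.start, seg.end):
                    ov = min(seg.end, w.end) - max(seg.start, w.start)
                    if ov > 0:
                        called_sum[w.index] += seg.total_cn * ov
                        called_len[w.index] += ov
        fill = (
            Fraction(fill_value) if fill_value is not None else as_fraction(ploidies[sample])
        )
        pn, pd_ = fill.numerator, fill.denominator
        for wi in range(n_win):
            num = pd_ * int(called_sum[wi]) + pn * int(win_len[wi] - called_len[wi])
            values[si, wi] = round_ratio_half_away(num, pd_ * int(win_len[wi]))
    return CNVMatrix(
        samples=tuple(samples), windows=windows, values=values, flavor="absolute"
    )


def to_relative(m: CNVMatrix, ploidies: PloidyTable) -> CNVMatrix:
    """Recentre an absolute matrix on per-sample ploidy and clamp to
    [-4, +6].  Entries equal to the (rounded) ploidy map to exactly 0."""
    if m.flavor != "absolute":
        raise ValueError("to_relative expects an absolute matrix")
    missing = [s for s in m.samples if s not in ploidies]
    if missing:
        raise KeyError(f"samples missing from ploidy table: {missing}")
    out = np.empty_like(m.values)
    for si, sample in enumerate(m.samples):
        p = round_half_away(ploidies[sample])
        out[si] = np.clip(m.values[si] - p, RELATIVE_MIN, RELATIVE_MAX)
    return CNVMatrix(
        samples=m.samples, windows=m.windows, values=out, flavor="relative"
    )


def export_matrix(m: CNVMatrix, path: str) -> str:
    """Tab-delimited matrix export: samples as rows, ``chrom:start-end``
    window labels as columns."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(m.windows.labels) + "\n")
        for si, sample in enumerate(m.samples):
            fh.write(sample + "\t" + "\t".join(str(v) for v in m.values[si]) + "\n")
    return path
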