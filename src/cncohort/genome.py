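"""Genome builds and window partitions.

A :class:`GenomeBuild` holds ordered chromosome lengths and centromere
intervals; :func:`make_windows` tiles every chromosome into non-overlapping
windows of a fixed length (or a fixed percentage of each chromosome),
removes centromeric overlap, and merges undersized pieces so that every
window is at least half the nominal length — the partition that all
windowed copy-number matrices are built on.

Coordinates are 0-based half-open throughout the package.
"""
from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from typing import Iterable, Mapping, Sequence

BUNDLED_BUILDS = ("hg18", "hg19")

_SEX_RANK = {"X": 100, "Y": 101, "XY": 102, "M": 103, "MT": 103}


def strip_chr(name: str) -> str:
    """Drop a leading 'chr' prefix (case-insensitive)."""
    return name[3:] if name.lower().startswith("chr") else name


def chrom_sort_key(name: str):
    """Genomic ordering key: 1..22 numerically, then X, Y, M, then others."""
    base = strip_chr(str(name))
    if base.isdigit():
        return (0, int(base), "")
    if base.upper() in _SEX_RANK:
        return (0, _SEX_RANK[base.upper()], "")
    return (1, 0, base)


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths plus centromere intervals for one assembly."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("empty genome build")
        seen = set()
        lengths = {}
        for chrom, length in self.chromosomes:
            if chrom in seen:
                raise ValueError(f"duplicate chromosome {chrom!r}")
            seen.add(chrom)
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            lengths[chrom] = length
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere for unknown chromosome {chrom!r}")
            if not (0 <= cs < ce <= lengths[chrom]):
                raise ValueError(
                    f"centromere [{cs}, {ce}) outside chromosome {chrom!r} "
                    f"of length {lengths[chrom]}"
                )

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for c, l in self.chromosomes:
            if c == chrom:
                return l
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def normalize_chrom(self, raw: str) -> str:
        """Map an input chromosome name (with or without 'chr') to this
        build's canonical spelling."""
        raw = str(raw)
        names = set(self.chrom_names)
        for cand in (raw, strip_chr(raw), "chr" + raw):
            if cand in names:
                return cand
        raise KeyError(f"unknown chromosome {raw!r} for build {self.name}")

    def arms(self, chrom: str) -> list[tuple[int, int]]:
        """Chromosome minus centromere: one or two non-empty intervals."""
        length = self.length(chrom)
        cen = self.centromeres.get(chrom)
        if cen is None:
            return [(0, length)]
        cs, ce = cen
        out = []
        if cs > 0:
            out.append((0, cs))
        if ce < length:
            out.append((ce, length))
        return out

    def subset(self, chroms: Iterable[str]) -> "GenomeBuild":
        keep = set(chroms)
        return GenomeBuild(
            name=self.name,
            chromosomes=tuple((c, l) for c, l in self.chromosomes if c in keep),
            centromeres={c: v for c, v in self.centromeres.items() if c in keep},
        )


def _read_two_column(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def load_build(source, centromeres=None, name: str | None = None) -> GenomeBuild:
    """Load a genome build.

    ``source`` is either a bundled build name (``"hg18"``/``"hg19"``) or the
    path to a tab-delimited chromosome-sizes file (name, length); an optional
    ``centromeres`` path supplies (name, start, end) intervals, 0-based
    half-open.
    """
    if isinstance(source, str) and source in BUNDLED_BUILDS:
        ref = resources.files("cncohort").joinpath(f"data/{source}.build.tsv")
        chroms, cens = [], {}
        for line in ref.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            c, length, cs, ce = line.split("\t")
            chroms.append((c, int(length)))
            cens[c] = (int(cs), int(ce))
        return GenomeBuild(name=source, chromosomes=tuple(chroms), centromeres=cens)
    if isinstance(source, str) and not os.path.exists(source):
        raise ValueError(
            f"unknown build {source!r}: not one of {BUNDLED_BUILDS} and not a file"
        )
    chroms = []
    for row in _read_two_column(source):
        if len(row) < 2:
            raise ValueError(f"malformed chromosome-sizes row: {row!r}")
        chroms.append((row[0], int(row[1])))
    cens = {}
    if centromeres is not None:
        for row in _read_two_column(centromeres):
            if len(row) < 3:
                raise ValueError(f"malformed centromere row: {row!r}")
            cens[row[0]] = (int(row[1]), int(row[2]))
    return GenomeBuild(
        name=name or os.path.basename(str(source)),
        chromosomes=tuple(chroms),
        centromeres=cens,
    )


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class WindowSet:
    """Genome-wide ordered window partition (indices are genomic ordinals)."""

    build: GenomeBuild
    windows: tuple[Window, ...]

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]

    @cached_property
    def _chrom_index(self) -> dict[str, tuple[list[Window], list[int], list[int]]]:
        idx: dict[str, list[Window]] = {}
        for w in self.windows:
            idx.setdefault(w.chrom, []).append(w)
        return {
            c: (ws, [w.start for w in ws], [w.end for w in ws])
            for c, ws in idx.items()
        }

    def by_chrom(self, chrom: str) -> list[Window]:
        return list(self._chrom_index.get(chrom, ([], [], []))[0])

    def overlapping(self, chrom: str, start: int, end: int) -> list[Window]:
        """Windows of ``chrom`` intersecting [start, end)."""
        ws, starts, ends = self._chrom_index.get(chrom, ([], [], []))
        lo = bisect_right(ends, start)
        hi = bisect_left(starts, end)
        return ws[lo:hi]

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]


def _merge_undersized(pieces: list[tuple[int, int]], min_len2: int) -> list[tuple[int, int]]:
    """Merge pieces with 2*length < min_len2 into their upstream neighbour
    (downstream when first in the arm).  Terminates with either every piece
    compliant or a single piece spanning the whole arm."""
    pieces = list(pieces)
    while len(pieces) > 1:
        idx = next(
            (i for i, (s, e) in enumerate(pieces) if 2 * (e - s) < min_len2), None
        )
        if idx is None:
            break
        if idx > 0:
            s0, _ = pieces[idx - 1]
            _, e1 = pieces[idx]
            pieces[idx - 1 : idx + 1] = [(s0, e1)]
        else:
            s0, _ = pieces[0]
            _, e1 = pieces[1]
            pieces[0:2] = [(s0, e1)]
    return pieces


def make_windows(
    build: GenomeBuild,
    size: int | None = None,
    percent: float | None = None,
) -> WindowSet:
    """Tile every chromosome into non-overlapping windows.

    Exactly one of ``size`` (window length in bp) or ``percent`` (window
    length as a percentage of each chromosome's length) must be given.
    Each chromosome is tiled from position 0; any window overlapping the
    centromere is replaced by its arm pieces, and any piece shorter than
    half the nominal length — including the chromosome-terminal remainder —
    is merged with its nearest contiguous window on the same arm.  An arm
    shorter than half the nominal length yields a single window covering
    the arm.
    """
    if (size is None) == (percent is None):
        raise ValueError("specify exactly one of size or percent")
    if size is not None and size <= 0:
        raise ValueError("window size must be positive")
    if percent is not None and not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    if size is not None and all(l < size for _, l in build.chromosomes):
        raise ValueError("window size exceeds every chromosome length")

    windows: list[Window] = []
    index = 0
    for chrom, length in build.chromosomes:
        L = size if size is not None else max(1, int(percent / 100.0 * length))
        tiles = [(s, min(s + L, length)) for s in range(0, length, L)]
        for arm_start, arm_end in build.arms(chrom):
            pieces = []
            for s, e in tiles:
                ts, te = max(s, arm_start), min(e, arm_end)
                if te > ts:
                    pieces.append((ts, te))
            for s, e in _merge_undersized(pieces, L):
                windows.append(Window(chrom, s, e, index))
                index += 1
    return WindowSet(build=build, windows=tuple(windows))
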