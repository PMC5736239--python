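"""Reading and writing allele-specific segment calls and cohort tables.

Two input dialects are supported:

* **ascat** — a single tab-delimited file with one row per segment call
  (sample, chromosome, start, end, major-allele copies, minor-allele
  copies); coordinates are 1-based inclusive on disk and converted to
  0-based half-open internally.
* **sequenza** — a directory of per-sample ``*_segments.txt`` tables
  (columns ``chromosome``, ``start.pos``, ``end.pos``, ``CNt``, ``A``,
  ``B``).

Sample annotations (feature table with a ``Sample`` column) and per-sample
ploidies are plain TSVs.  A GISTIC-format segmentation export is provided
so recurrence statistics can be computed with the external tool.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from fractions import Fraction
from functools import cached_property
from glob import glob
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._util import as_fraction
from .genome import GenomeBuild, chrom_sort_key, strip_chr

log = logging.getLogger(__name__)

# header synonyms accepted for the ascat dialect (matched lowercased,
# dots/underscores stripped)
_ASCAT_SYNONYMS = {
    "sample": {"sample", "samplename", "sampleid", "id"},
    "chrom": {"chr", "chrom", "chromosome"},
    "start": {"start", "startpos"},
    "end": {"end", "endpos"},
    "n_major": {"nmajor", "major", "na", "nmaj"},
    "n_minor": {"nminor", "minor", "nb", "nmin"},
}


@dataclass(frozen=True, order=True)
class CopyNumberSegment:
    """One allele-specific copy-number call for one sample.

    ``n_major``/``n_minor`` are the integer copies of the more/less
    abundant parental allele; total copy number is their sum.
    Coordinates are 0-based half-open.
    """

    sample: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"{self.sample} {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValueError(
                f"{self.sample} {self.chrom}:{self.start}-{self.end}: "
                f"require n_major >= n_minor >= 0, got "
                f"({self.n_major}, {self.n_minor})"
            )

    @property
    def total_cn(self) -> int:
        return self.n_major + self.n_minor

    @property
    def length(self) -> int:
        return self.end - self.start


def _canonical_sort_key(seg: CopyNumberSegment):
    return (seg.sample, chrom_sort_key(seg.chrom), seg.start, seg.end)


@dataclass(frozen=True)
class SegmentSet:
    """An immutable, canonically sorted collection of segment calls.

    Within one sample the calls are validated to be pairwise
    non-overlapping, which every allele-specific caller guarantees.
    """

    segments: tuple[CopyNumberSegment, ...]

    @classmethod
    def from_iterable(cls, segs: Iterable[CopyNumberSegment]) -> "SegmentSet":
        ordered = tuple(sorted(segs, key=_canonical_sort_key))
        prev = None
        for seg in ordered:
            if (
                prev is not None
                and seg.sample == prev.sample
                and seg.chrom == prev.chrom
                and seg.start < prev.end
            ):
                raise ValueError(
                    f"overlapping calls for sample {seg.sample!r} on "
                    f"{seg.chrom}: [{prev.start},{prev.end}) and "
                    f"[{seg.start},{seg.end})"
                )
            prev = seg
        return cls(segments=ordered)

    def __len__(self):
        return len(self.segments)

    def __iter__(self) -> Iterator[CopyNumberSegment]:
        return iter(self.segments)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({s.sample for s in self.segments}))

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted({s.chrom for s in self.segments}, key=chrom_sort_key))

    @cached_property
    def _by_sample_chrom(self) -> dict[tuple[str, str], list[CopyNumberSegment]]:
        out: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        for seg in self.segments:
            out.setdefault((seg.sample, seg.chrom), []).append(seg)
        return out

    def of(self, sample: str, chrom: str | None = None) -> list[CopyNumberSegment]:
        if chrom is not None:
            return list(self._by_sample_chrom.get((sample, chrom), []))
        return [s for s in self.segments if s.sample == sample]

    def covered_length(self, sample: str) -> int:
        return sum(s.length for s in self.segments if s.sample == sample)

    def filter_samples(
        self,
        exclude: Iterable[str] = (),
        include: Iterable[str] | None = None,
    ) -> "SegmentSet":
        exclude = set(exclude)
        include = None if include is None else set(include)
        kept = [
            s
            for s in self.segments
            if s.sample not in exclude and (include is None or s.sample in include)
        ]
        return SegmentSet(segments=tuple(kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [s.sample for s in self.segments],
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "n_major": [s.n_major for s in self.segments],
                "n_minor": [s.n_minor for s in self.segments],
                "total_cn": [s.total_cn for s in self.segments],
            }
        )


class PloidyTable(Mapping):
    """Per-sample ploidies (positive rationals; fractional after tie-averaging)."""

    def __init__(self, mapping: Mapping[str, object]):
        data = {}
        for sample, p in mapping.items():
            f = as_fraction(p)
            if f <= 0:
                raise ValueError(f"non-positive ploidy {p!r} for sample {sample!r}")
            data[str(sample)] = f
        self._data = data

    @classmethod
    def from_constant(cls, value, samples: Iterable[str]) -> "PloidyTable":
        return cls({s: value for s in samples})

    def __getitem__(self, sample: str) -> Fraction:
        return self._data[sample]

    def __iter__(self):
        return iter(self._data)

    def __len__(self):
        return len(self._data)

    def __repr__(self):
        return f"PloidyTable({dict(self._data)!r})"

    def updated(self, other: Mapping[str, object] | None) -> "PloidyTable":
        """New table where ``other``'s entries take per-sample precedence."""
        if not other:
            return self
        merged = dict(self._data)
        merged.update({str(k): as_fraction(v) for k, v in other.items()})
        return PloidyTable(merged)


class SampleTable:
    """Sample annotations: a ``Sample`` column plus arbitrary feature columns.

    When an alias column is present the alias becomes the official sample
    identifier.
    """

    def __init__(self, df: pd.DataFrame):
        cols = {c.lower(): c for c in df.columns}
        if "sample" not in cols:
            raise ValueError("sample annotation file must have a 'Sample' column")
        df = df.copy()
        sample_col = cols["sample"]
        alias_col = cols.get("alias") or cols.get("samplealias")
        official = df[alias_col] if alias_col is not None else df[sample_col]
        df.index = official.astype(str)
        drop = [sample_col] + ([alias_col] if alias_col else [])
        self.df = df.drop(columns=drop)

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def features(self) -> list[str]:
        return list(self.df.columns)

    def value(self, sample: str, feature: str):
        if feature not in self.df.columns:
            raise KeyError(f"unknown feature {feature!r}")
        return self.df.loc[sample, feature]

    def values_for(self, feature: str, samples: Iterable[str]) -> list:
        if feature not in self.df.columns:
            raise KeyError(f"unknown feature {feature!r}")
        return [
            self.df.loc[s, feature] if s in self.df.index else None for s in samples
        ]


def _norm_header(name: str) -> str:
    return str(name).strip().lower().replace(".", "").replace("_", "").replace(" ", "")


def _map_ascat_columns(columns) -> dict[str, str]:
    mapping = {}
    for internal, synonyms in _ASCAT_SYNONYMS.items():
        for col in columns:
            if _norm_header(col) in synonyms:
                mapping[internal] = col
                break
        else:
            raise ValueError(
                f"missing column for {internal!r}; got header {list(columns)!r}"
            )
    return mapping


def _normalize_chrom(raw: str, build: GenomeBuild | None) -> str:
    if build is not None:
        return build.normalize_chrom(raw)
    return strip_chr(str(raw))


def parse_segments(
    path: str,
    dialect: str = "ascat",
    build: GenomeBuild | None = None,
) -> SegmentSet:
    """Parse segment calls from an ascat-dialect file or a sequenza-dialect
    per-sample directory into a validated :class:`SegmentSet`."""
    if dialect == "ascat":
        return _parse_ascat(path, build)
    if dialect == "sequenza":
        return _parse_sequenza_dir(path, build)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_ascat(path: str, build: GenomeBuild | None) -> SegmentSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _map_ascat_columns(df.columns)
    segs = []
    for _, row in df.iterrows():
        start = int(row[cols["start"]])
        end = int(row[cols["end"]])
        segs.append(
            CopyNumberSegment(
                sample=str(row[cols["sample"]]),
                chrom=_normalize_chrom(row[cols["chrom"]], build),
                start=start - 1,  # 1-based inclusive on disk
                end=end,
                n_major=int(row[cols["n_major"]]),
                n_minor=int(row[cols["n_minor"]]),
            )
        )
    return SegmentSet.from_iterable(segs)


def _parse_sequenza_dir(path: str, build: GenomeBuild | None) -> SegmentSet:
    if not os.path.isdir(path):
        raise ValueError(f"sequenza dialect expects a directory, got {path!r}")
    files = sorted(glob(os.path.join(path, "*_segments.txt")))
    if not files:
        raise ValueError(f"no *_segments.txt files under {path!r}")
    segs = []
    for fn in files:
        sample = os.path.basename(fn)[: -len("_segments.txt")]
        df = pd.read_csv(fn, sep="\t")
        need = {"chromosome", "start.pos", "end.pos", "CNt"}
        if not need.issubset(df.columns):
            raise ValueError(f"{fn}: missing columns {sorted(need - set(df.columns))}")
        for _, row in df.iterrows():
            total = int(row["CNt"])
            a = row.get("A")
            b = row.get("B")
            if b is None or (isinstance(b, float) and math.isnan(b)):
                log.warning("%s: missing minor-allele copies, assuming 0", fn)
                b = 0
            if a is None or (isinstance(a, float) and math.isnan(a)):
                a = total - int(b)
            segs.append(
                CopyNumberSegment(
                    sample=sample,
                    chrom=_normalize_chrom(row["chromosome"], build),
                    start=int(row["start.pos"]) - 1,
                    end=int(row["end.pos"]),
                    n_major=int(a),
                    n_minor=int(b),
                )
            )
    return SegmentSet.from_iterable(segs)


def write_ascat_segments(segs: SegmentSet, path: str) -> str:
    """Write the ascat dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("sample\tchr\tstartpos\tendpos\tnMajor\tnMinor\n")
        for s in segs:
            fh.write(
                f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                f"{s.n_major}\t{s.n_minor}\n"
            )
    return path


def write_sequenza_dir(segs: SegmentSet, out_dir: str) -> list[str]:
    """Write the sequenza dialect: one ``<sample>_segments.txt`` per sample."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for sample in segs.samples:
        fn = os.path.join(out_dir, f"{sample}_segments.txt")
        with open(fn, "w") as fh:
            fh.write("chromosome\tstart.pos\tend.pos\tCNt\tA\tB\n")
            for s in segs:
                if s.sample != sample:
                    continue
                fh.write(
                    f"{s.chrom}\t{s.start + 1}\t{s.end}\t{s.total_cn}\t"
                    f"{s.n_major}\t{s.n_minor}\n"
                )
        paths.append(fn)
    return paths


def read_sample_table(path: str) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def read_ploidy_table(source, samples: Iterable[str] | None = None) -> PloidyTable:
    """Read a ploidy file (columns ``sample``, ``ploidy``), or broadcast a
    single numeric value to every sample in ``samples``."""
    text = str(source)
    try:
        value = float(text)
    except ValueError:
        value = None
    if value is not None:
        if samples is None:
            raise ValueError("broadcasting a constant ploidy requires sample names")
        return PloidyTable.from_constant(value, samples)
    df = pd.read_csv(source, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "ploidy" not in cols:
        raise ValueError("ploidy file needs 'sample' and 'ploidy' columns")
    try:
        values = [as_fraction(float(v)) for v in df[cols["ploidy"]]]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric ploidy in {source!r}") from exc
    return PloidyTable(dict(zip(df[cols["sample"]].astype(str), values)))


def read_tables(
    sample_file: str | None = None,
    ploidy_file: str | None = None,
    samples: Iterable[str] | None = None,
) -> tuple[SampleTable | None, PloidyTable | None]:
    sample_table = read_sample_table(sample_file) if sample_file else None
    ploidy_table = (
        read_ploidy_table(ploidy_file, samples) if ploidy_file is not None else None
    )
    return sample_table, ploidy_table


def export_gistic_segments(
    segs: SegmentSet,
    out: str,
    zero_floor: float = 0.1,
    marker_bp: int = 10_000,
    min_markers: int = 5,
) -> str:
    """Write the six-column GISTIC segmentation format.

    seg.mean is log2(total_cn / 2) with zero totals floored at
    ``zero_floor``; the marker count is a surrogate of one marker per
    ``marker_bp`` bases (at least ``min_markers``).
    """
    if len(segs) == 0:
        raise ValueError("empty segment set")
    with open(out, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for s in segs:
            total = s.total_cn if s.total_cn > 0 else zero_floor
            markers = max(min_markers, s.length // marker_bp)
            fh.write(
                f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{markers}\t"
                f"{math.log2(total / 2.0):.6f}\n"
            )
    return out
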