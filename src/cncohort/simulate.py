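"""Synthetic cohorts of allele-specific segment calls with known truth.

The generator emulates the *output* of an allele-specific caller on a
tumour cohort — not the underlying array/sequencing signal: every sample
gets a baseline at its planted ploidy (allele split ceil/floor of p/2),
recurrent events (gains, losses, cn-LOH) overwrite the baseline on an
exact number of carrier samples, contiguous coverage gaps remove calls,
and optional fragmentation splits calls without changing values.  The
generator is noise-free and fully deterministic given its seed, so
planted frequencies and ploidies are exactly recoverable — which is what
makes it usable as ground truth in tests.

Coverage gaps are placed inside event-free regions so that planted event
frequencies remain exact under partial coverage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._util import round_half_away
from .genome import GenomeBuild, load_build
from .io import (
    CopyNumberSegment,
    SegmentSet,
    write_ascat_segments,
    write_sequenza_dir,
)

CN_LOH = "cn-loh"


@dataclass(frozen=True)
class PlantedEvent:
    """A recurrent aberration planted in a fixed fraction of samples.

    ``change`` is a relative copy-number change (int, may be negative) or
    the string ``"cn-loh"`` for a copy-neutral LOH event.
    """

    chrom: str
    start: int
    end: int
    change: int | str
    fraction: float
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.fraction <= 1):
            raise ValueError("fraction must be in [0, 1]")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        if not (self.change == CN_LOH or isinstance(self.change, int)):
            raise ValueError(f"change must be an int or {CN_LOH!r}")

    def overlaps(self, other: "PlantedEvent") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_samples: int
    build: str | GenomeBuild = "hg19"
    ploidies: tuple[tuple[int, float], ...] = ((2, 1.0),)  # (ploidy, fraction)
    events: tuple[PlantedEvent, ...] = ()
    gap_rate: float = 0.0  # fraction of each chromosome left uncovered
    frag_rate: float = 0.0  # expected extra breakpoints per Mb per sample
    seed: int = 0
    sample_prefix: str = "S"


@dataclass(frozen=True)
class CohortTruth:
    """Exact ground truth for a generated cohort."""

    ploidies: dict
    carriers: dict  # event name -> tuple of carrier samples


def _event_name(ev: PlantedEvent, idx: int) -> str:
    return ev.name or f"event{idx}"


def _assign_ploidies(spec: CohortSpec, samples, rng) -> dict[str, int]:
    counts = [round(frac * spec.n_samples) for _, frac in spec.ploidies]
    # fix rounding drift on the last class
    counts[-1] = spec.n_samples - sum(counts[:-1])
    if min(counts) < 0:
        raise ValueError("ploidy fractions do not fit the cohort size")
    order = list(samples)
    rng.shuffle(order)
    out = {}
    pos = 0
    for (p, _), c in zip(spec.ploidies, counts):
        for s in order[pos : pos + c]:
            out[s] = int(p)
        pos += c
    return out


def _apply_event(
    intervals: list[tuple[int, int, int, int]],
    start: int,
    end: int,
    maj: int,
    mino: int,
) -> list[tuple[int, int, int, int]]:
    """Overwrite [start, end) of a per-chromosome interval list with the
    given allele copies; values are (s, e, n_major, n_minor)."""
    out = []
    for s, e, a, b in intervals:
        if e <= start or s >= end:
            out.append((s, e, a, b))
            continue
        if s < start:
            out.append((s, start, a, b))
        if e > end:
            out.append((end, e, a, b))
    out.append((start, end, maj, mino))
    return sorted(out)


def _event_alleles(change, p: int, base_maj: int, base_min: int) -> tuple[int, int]:
    if change == CN_LOH:
        return max(round_half_away(p), 1), 0
    c = int(change)
    if c >= 0:
        return base_maj + c, base_min  # extra copies on the major allele
    # losses remove minor-allele copies first
    new_min = max(base_min + c, 0)
    left = -c - (base_min - new_min)
    new_maj = max(base_maj - left, 0)
    return new_maj, new_min


def _gap_regions(build: GenomeBuild, events: Sequence[PlantedEvent], chrom: str):
    """Event-free intervals of a chromosome (candidate gap locations)."""
    length = build.length(chrom)
    blocks = sorted(
        (ev.start, ev.end) for ev in events if ev.chrom == chrom
    )
    free = []
    cursor = 0
    for s, e in blocks:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        free.append((cursor, length))
    return free


def generate_cohort(spec: CohortSpec) -> tuple[SegmentSet, CohortTruth]:
    """Generate a cohort and its exact ground truth (deterministic per seed)."""
    build = spec.build if isinstance(spec.build, GenomeBuild) else load_build(spec.build)
    for ev in spec.events:
        build.normalize_chrom(ev.chrom)
        if ev.end > build.length(ev.chrom):
            raise ValueError(f"event {ev} outside chromosome")
    rng = np.random.default_rng(spec.seed)
    samples = [f"{spec.sample_prefix}{i + 1:03d}" for i in range(spec.n_samples)]
    ploidies = _assign_ploidies(spec, samples, rng)

    # carrier selection: exact counts; events with overlapping intervals get
    # disjoint carrier sets (a sample cannot carry two conflicting states)
    carriers: dict[str, tuple[str, ...]] = {}
    carrier_events: dict[str, list[PlantedEvent]] = {s: [] for s in samples}
    for idx, ev in enumerate(spec.events):
        want = round(ev.fraction * spec.n_samples)
        order = list(samples)
        rng.shuffle(order)
        eligible = [
            s
            for s in order
            if not any(ev.overlaps(prev) for prev in carrier_events[s])
        ]
        if len(eligible) < want:
            raise ValueError(
                f"contradictory overlapping events: cannot place "
                f"{_event_name(ev, idx)} on {want} samples"
            )
        chosen = eligible[:want]
        for s in chosen:
            carrier_events[s].append(ev)
        carriers[_event_name(ev, idx)] = tuple(sorted(chosen))

    # per-chromosome gap location templates are drawn per sample
    segs: list[CopyNumberSegment] = []
    for sample in samples:
        p = ploidies[sample]
        base_maj = (p + 1) // 2
        base_min = p // 2
        for chrom, length in build.chromosomes:
            intervals = [(0, length, base_maj, base_min)]
            for ev in carrier_events[sample]:
                if ev.chrom != chrom:
                    continue
                maj, mino = _event_alleles(ev.change, p, base_maj, base_min)
                if mino > maj:
                    maj, mino = mino, maj
                intervals = _apply_event(intervals, ev.start, ev.end, maj, mino)
            # coverage gap: one contiguous uncovered stretch per chromosome
            if spec.gap_rate > 0:
                gap_len = int(spec.gap_rate * length)
                free = _gap_regions(build, spec.events, chrom)
                free = sorted(free, key=lambda r: r[1] - r[0], reverse=True)
                if free and gap_len > 0:
                    fs, fe = free[0]
                    glen = min(gap_len, fe - fs)
                    gs = fs + int(rng.integers(0, fe - fs - glen + 1))
                    intervals = [
                        piece
                        for s0, e0, a, b in intervals
                        for piece in (
                            ((s0, min(e0, gs), a, b),) if s0 < min(e0, gs) else ()
                        )
                    ] + [
                        (max(s0, gs + glen), e0, a, b)
                        for s0, e0, a, b in intervals
                        if e0 > max(s0, gs + glen)
                    ]
                    intervals = sorted(set(intervals))
            # fragmentation: split calls without changing values
            if spec.frag_rate > 0:
                n_breaks = int(rng.poisson(spec.frag_rate * length / 1e6))
                breaks = sorted(int(b) for b in rng.integers(0, length, n_breaks))
                for bp in breaks:
                    intervals = [
                        part
                        for s0, e0, a, b in intervals
                        for part in (
                            [(s0, bp, a, b), (bp, e0, a, b)]
                            if s0 < bp < e0
                            else [(s0, e0, a, b)]
                        )
                    ]
            for s0, e0, maj, mino in intervals:
                segs.append(
                    CopyNumberSegment(
                        sample=sample,
                        chrom=chrom,
                        start=s0,
                        end=e0,
                        n_major=maj,
                        n_minor=mino,
                    )
                )
    truth = CohortTruth(
        ploidies={s: ploidies[s] for s in samples}, carriers=carriers
    )
    return SegmentSet.from_iterable(segs), truth


def write_fixture_files(segs: SegmentSet, dialect: str, out_dir: str):
    """Serialize a cohort in either input dialect (round-trips through the
    parsers)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    if dialect == "ascat":
        return write_ascat_segments(segs, os.path.join(out_dir, "segments.tsv"))
    if dialect == "sequenza":
        return write_sequenza_dir(segs, out_dir)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Bundled preset: an HCC-like cohort of 96 samples on hg19, with the q arms
# of chromosomes 1 and 8 sharing a similar total gain frequency (50%) but
# very different gain magnitudes (>= +4 in 7/96 vs 24/96 samples), an 8p
# loss, and a 17p cn-LOH region.
# ---------------------------------------------------------------------------

HCC_N = 96
HCC_REGION_1Q = ("1", 124_535_434, 249_250_621)
HCC_REGION_8Q = ("8", 46_838_887, 146_364_022)
HCC_REGION_8P = ("8", 0, 43_838_887)
HCC_REGION_17P = ("17", 0, 22_263_006)
HCC_GE4_CARRIERS_1Q = 7
HCC_GE4_CARRIERS_8Q = 24
HCC_CNLOH_CARRIERS_17P = 29


def hcc_like_spec(seed: int = 20171219) -> CohortSpec:
    """The bundled HCC-like study preset (96 samples, hg19)."""
    n = HCC_N
    ev = []
    c1, s1, e1 = HCC_REGION_1Q
    ev.append(PlantedEvent(c1, s1, e1, 4, HCC_GE4_CARRIERS_1Q / n, "1q_gain_ge4"))
    ev.append(PlantedEvent(c1, s1, e1, 1, 25 / n, "1q_gain_p1"))
    ev.append(PlantedEvent(c1, s1, e1, 2, 16 / n, "1q_gain_p2"))
    c8, s8, e8 = HCC_REGION_8Q
    ev.append(PlantedEvent(c8, s8, e8, 4, HCC_GE4_CARRIERS_8Q / n, "8q_gain_ge4"))
    ev.append(PlantedEvent(c8, s8, e8, 1, 12 / n, "8q_gain_p1"))
    ev.append(PlantedEvent(c8, s8, e8, 2, 12 / n, "8q_gain_p2"))
    cp, sp, ep = HCC_REGION_8P
    ev.append(PlantedEvent(cp, sp, ep, -1, 38 / n, "8p_loss"))
    cl, sl, el = HCC_REGION_17P
    ev.append(
        PlantedEvent(cl, sl, el, CN_LOH, HCC_CNLOH_CARRIERS_17P / n, "17p_cnloh")
    )
    return CohortSpec(
        n_samples=n,
        build="hg19",
        ploidies=((2, 70 / n), (4, 26 / n)),
        events=tuple(ev),
        gap_rate=0.05,
        frag_rate=0.001,
        seed=seed,
        sample_prefix="HCC",
    )
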