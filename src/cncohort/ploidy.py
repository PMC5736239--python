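"""Sample ploidy estimation.

A sample's ploidy is estimated as the modal copy-number value of a coarse
windowed matrix built at 10%-of-chromosome resolution, with uncovered bases
filled at a default copy number of 2 (at this window size the fill has
little influence on window values).  When several values tie for the
maximal frequency the ploidy is the arithmetic mean of the tied values,
which may therefore be fractional (e.g. 2.5).
"""
from __future__ import annotations

from collections import Counter
from fractions import Fraction
from typing import Mapping

from .genome import GenomeBuild, make_windows
from .io import PloidyTable, SegmentSet
from .matrix import build_matrix

DEFAULT_FILL = 2
PLOIDY_WINDOW_PERCENT = 10.0

_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def estimate_ploidies(
    segs: SegmentSet,
    build: GenomeBuild,
    default_fill: int = DEFAULT_FILL,
    user_ploidies: Mapping | None = None,
    include_sex: bool = True,
) -> PloidyTable:
    """Estimate every sample's ploidy from its windowed copy numbers.

    Windows from all chromosomes are pooled genome-wide; chromosomes with
    no calls still contribute windows at the default fill.  Entries of
    ``user_ploidies`` take per-sample precedence over the estimate.
    """
    b = build if include_sex else build.subset(
        c for c in build.chrom_names if c not in _SEX_CHROMS
    )
    windows = make_windows(b, percent=PLOIDY_WINDOW_PERCENT)
    if len(windows) == 0:
        raise ValueError("genome build produced no windows")
    mp = build_matrix(segs, windows, fill_value=default_fill)
    estimates: dict[str, Fraction] = {}
    for si, sample in enumerate(mp.samples):
        counts = Counter(int(v) for v in mp.values[si])
        top = max(counts.values())
        tied = sorted(v for v, c in counts.items() if c == top)
        estimates[sample] = Fraction(sum(tied), len(tied))
    return PloidyTable(estimates).updated(user_ploidies)


def write_ploidies(ploidies: PloidyTable, path: str) -> str:
    from ._util import fmt_number

    with open(path, "w") as fh:
        fh.write("sample\tploidy\n")
        for sample in sorted(ploidies):
            fh.write(f"{sample}\t{fmt_number(ploidies[sample])}\n")
    return path
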