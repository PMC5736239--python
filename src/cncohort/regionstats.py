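"""Region-wise gain-category tabulation and Fisher exact comparison.

Given two named genomic regions (e.g. the q arms of chromosomes 1 and 8),
each sample is assigned the length-weighted modal relative copy-number
category it carries over the region, the categories are binned (default
+1, +2, +3, ">=+4"), and the two regions are compared with an exact Fisher
test on the resulting categories x regions contingency table.

The two-sided 2x2 p-value is the sum of hypergeometric probabilities of
all tables (with the observed margins) no more probable than the observed
one — computed in exact integer arithmetic.  r x 2 tables are handled by
exhaustive enumeration of same-margin tables up to a configurable total,
falling back to seeded Monte-Carlo sampling beyond it.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PloidyTable
from .segments import SegmentMatrix, classify_cells

log = logging.getLogger(__name__)

DEFAULT_CATEGORIES = "1,2,3,4+"
NO_GAIN_LABEL = "no gain"


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (0-based half-open)."""
    chrom, _, span = text.partition(":")
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


@dataclass(frozen=True)
class CategoryBin:
    label: str
    low: int
    high: int | None  # None = open-ended

    def contains(self, category: int) -> bool:
        if self.high is None:
            return category >= self.low
        return self.low <= category <= self.high


def parse_category_bins(spec: str | Sequence) -> list[CategoryBin]:
    """Parse a binning spec like ``"1,2,3,4+"`` or ``"1-3,4+"``.

    Tokens: ``k`` (exact), ``a-b`` (inclusive range), ``k+`` (at least k).
    """
    if not isinstance(spec, str):
        spec = ",".join(str(t) for t in spec)
    bins = []
    for token in spec.split(","):
        token = token.strip()
        if token.endswith("+"):
            low = int(token[:-1])
            bins.append(CategoryBin(label=f">=+{low}", low=low, high=None))
        elif "-" in token[1:]:
            a, b = token.split("-", 1)
            bins.append(
                CategoryBin(label=f"+{int(a)}..+{int(b)}", low=int(a), high=int(b))
            )
        else:
            v = int(token)
            bins.append(CategoryBin(label=f"{v:+d}", low=v, high=v))
    if not bins:
        raise ValueError(f"empty category spec {spec!r}")
    return bins


@dataclass(frozen=True)
class ContingencyTable:
    """Categories (rows) x regions (columns) sample counts."""

    df: pd.DataFrame

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy(dtype=np.int64)

    def to_tsv(self, path: str) -> str:
        self.df.to_csv(path, sep="\t")
        return path


def sample_region_category(
    ms: SegmentMatrix, sample: str, region: tuple[str, int, int]
) -> tuple[int | None, int]:
    """Length-weighted modal relative category of ``sample`` over ``region``.

    Returns (category, covered length); category is None when the sample
    has no call in the region.  Ties go to the higher category.
    """
    chrom, start, end = region
    weights: dict[int, int] = {}
    for i in ms.overlapping(chrom, start, end):
        ev = ms.events.get((i, sample)) if ms.events else None
        if ev is None:
            continue
        c, s, e = ms.intervals[i]
        ov = min(e, end) - max(s, start)
        weights[ev.category] = weights.get(ev.category, 0) + ov
    if not weights:
        return None, 0
    covered = sum(weights.values())
    best = max(weights.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0], covered


def gain_category_table(
    ms: SegmentMatrix,
    ploidies: PloidyTable | None,
    region_a: tuple[str, int, int] | str,
    region_b: tuple[str, int, int] | str,
    categories: str | Sequence = DEFAULT_CATEGORIES,
    include_no_gain: bool = False,
    region_names: tuple[str, str] | None = None,
    aggregator: str = "mode",
) -> ContingencyTable:
    """Count samples per gain-category bin in each of two regions.

    ``aggregator`` is ``"mode"`` (length-weighted modal category, default)
    or ``"max"`` (highest category carried anywhere in the region).
    """
    if ms.events is None:
        if ploidies is None:
            raise ValueError("unclassified segment matrix and no ploidies")
        ms = classify_cells(ms, ploidies)
    regions = []
    for r in (region_a, region_b):
        regions.append(parse_region(r) if isinstance(r, str) else tuple(r))
    names = region_names or tuple(
        f"{c}:{s}-{e}" for c, s, e in regions
    )
    bins = parse_category_bins(categories)
    labels = [b.label for b in bins] + ([NO_GAIN_LABEL] if include_no_gain else [])
    counts = pd.DataFrame(0, index=labels, columns=list(names), dtype=np.int64)
    for region, name in zip(regions, names):
        if not ms.overlapping(*region):
            raise ValueError(f"region {name} overlaps no segment")
        for sample in ms.samples:
            if aggregator == "mode":
                # weights are binned first, so split gain levels inside one
                # bin still count together
                cat = _modal_bin(ms, sample, region, bins)
            elif aggregator == "max":
                cat = _max_bin(ms, sample, region, bins)
            else:
                raise ValueError(f"unknown aggregator {aggregator!r}")
            if cat is None:
                continue
            if cat == NO_GAIN_LABEL and not include_no_gain:
                continue
            counts.loc[cat, name] += 1
    return ContingencyTable(df=counts)


def _bin_weights(ms, sample, region, bins):
    chrom, start, end = region
    weights: dict[str, int] = {}
    for i in ms.overlapping(chrom, start, end):
        ev = ms.events.get((i, sample))
        if ev is None:
            continue
        c, s, e = ms.intervals[i]
        ov = min(e, end) - max(s, start)
        label = next((b.label for b in bins if b.contains(ev.category)), None)
        if label is None:
            label = NO_GAIN_LABEL
        weights[label] = weights.get(label, 0) + ov
    return weights


def _modal_bin(ms, sample, region, bins):
    weights = _bin_weights(ms, sample, region, bins)
    if not weights:
        return None
    rank = {b.label: k for k, b in enumerate(bins)}
    rank[NO_GAIN_LABEL] = -1
    return max(weights.items(), key=lambda kv: (kv[1], rank[kv[0]]))[0]


def _max_bin(ms, sample, region, bins):
    weights = _bin_weights(ms, sample, region, bins)
    if not weights:
        return None
    rank = {b.label: k for k, b in enumerate(bins)}
    rank[NO_GAIN_LABEL] = -1
    return max(weights, key=lambda lbl: rank[lbl])


def _table_counts(t) -> np.ndarray:
    if isinstance(t, ContingencyTable):
        return t.counts
    return np.asarray(t, dtype=np.int64)


def fisher_exact(
    table,
    seed: int = 0,
    max_enumeration_total: int = 200,
    n_replicates: int = 100_000,
) -> float:
    """Two-sided Fisher exact p-value for an r x 2 contingency table.

    Exact by enumeration of all tables with the observed margins
    (probability-ordering convention: sum P over tables with
    P <= P(observed)).  Tables with total above ``max_enumeration_total``
    are evaluated by Monte-Carlo sampling from the multivariate
    hypergeometric null with the given seed; the replicate count is
    logged.  Degenerate margins give p = 1 with a warning.
    """
    counts = _table_counts(table)
    if counts.ndim != 2 or counts.shape[1] != 2:
        if counts.ndim == 2 and counts.shape[0] == 2:
            counts = counts.T
        else:
            raise ValueError("fisher_exact expects an r x 2 (or 2 x r) table")
    if (counts < 0).any():
        raise ValueError("negative counts")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        warnings.warn("degenerate margins (empty row or column): p = 1")
        return 1.0
    n = int(counts.sum())
    c1 = int(col_sums[0])
    rows = [int(r) for r in row_sums]
    a_obs = [int(x) for x in counts[:, 0]]
    w_obs = 1
    for r, a in zip(rows, a_obs):
        w_obs *= comb(r, a)
    if n <= max_enumeration_total:
        total_w = 0
        hit_w = 0
        stack = [(0, c1, 1)]
        while stack:
            idx, rem, w = stack.pop()
            if idx == len(rows) - 1:
                if rem <= rows[idx]:
                    w_full = w * comb(rows[idx], rem)
                    total_w += w_full
                    if w_full <= w_obs:
                        hit_w += w_full
                continue
            tail = sum(rows[idx + 1 :])
            lo = max(0, rem - tail)
            hi = min(rows[idx], rem)
            for a in range(lo, hi + 1):
                stack.append((idx + 1, rem - a, w * comb(rows[idx], a)))
        p = Fraction(hit_w, total_w)
        return float(p)
    # Monte-Carlo: draw column-1 allocations from the null
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(rows, c1, size=n_replicates)
    logw_obs = sum(_log_comb(r, a) for r, a in zip(rows, a_obs))
    logw = np.zeros(n_replicates)
    for ri, r in enumerate(rows):
        logw += _LOG_COMB_TABLE(r)[draws[:, ri]]
    hits = int((logw <= logw_obs + 1e-9).sum())
    log.info(
        "fisher_exact: Monte-Carlo with %d replicates (seed %d)",
        n_replicates,
        seed,
    )
    return (hits + 1) / (n_replicates + 1)


def _log_comb(r: int, a: int) -> float:
    from math import lgamma

    return lgamma(r + 1) - lgamma(a + 1) - lgamma(r - a + 1)


def _LOG_COMB_TABLE(r: int) -> np.ndarray:
    from scipy.special import gammaln

    a = np.arange(r + 1)
    return gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
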