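"""Matplotlib rendering of the three figure types.

Every figure has a text twin (matrix/event exports) carrying the same
information; plots are presentation only and carry no acceptance burden.
"""
from __future__ import annotations

import re
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .cluster import Dendrogram, HeatmapLayout
from .histogram import DISPLAY_TOP_BIN, HistogramTable, LineTrack, display_bin

DEFAULT_COLORS = {
    "+1": "#fdd49e",
    "+2": "#fc8d59",
    "+3": "#d7301f",
    ">=+4": "#7f0000",
    "-1": "#c6dbef",
    "-2": "#6baed6",
    "-3": "#2171b5",
    "-4": "#08306b",
    "cn-LOH": "#000000",
    "LOH": "#1f77b4",
    "het-gain": "#d7301f",
    "het-neutral": "#bdbdbd",
    "het-loss": "#2171b5",
    "hom-gain": "#7f0000",
    "hom-neutral": "#636363",
    "hom-loss": "#08306b",
}

DEFAULT_FORMATS = {
    "hist": ("png", {"width": 4000, "height": 1800, "res": 300}),
    "hetHom": ("png", {"width": 4000, "height": 1800, "res": 300}),
    "dend": ("png", {"width": 4000, "height": 2200, "res": 300}),
    "heat": ("pdf", {"width": 10, "height": 12}),
}

_FMT_RE = re.compile(r"(?P<key>\w+):(?P<fmt>\w+)(?:\((?P<args>[^)]*)\))?")


def read_color_file(path: str) -> dict:
    """Two-column (key, color) overrides for the default palette."""
    colors = dict(DEFAULT_COLORS)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("\t")
            colors[key.strip()] = value.strip()
    return colors


def parse_output_format(spec: str | None) -> dict:
    """Parse 'plotkey:format(width=...,height=...,res=...)' clauses
    separated by ';'.  Unknown keys fall back to defaults with a warning."""
    out = {k: (f, dict(kw)) for k, (f, kw) in DEFAULT_FORMATS.items()}
    if not spec:
        return out
    import warnings

    for clause in spec.split(";"):
        clause = clause.strip()
        if not clause:
            continue
        m = _FMT_RE.match(clause)
        if not m or m.group("key") not in out:
            warnings.warn(f"unrecognized output-format clause {clause!r}; ignored")
            continue
        kwargs = {}
        if m.group("args"):
            for part in m.group("args").split(","):
                k, _, v = part.partition("=")
                kwargs[k.strip()] = float(v)
        out[m.group("key")] = (m.group("fmt"), kwargs)
    return out


def _figsize(fmt: str, kwargs: Mapping) -> tuple[tuple[float, float], int]:
    if fmt in ("png", "tiff", "bmp", "jpg", "jpeg"):
        res = int(kwargs.get("res", 300))
        w = kwargs.get("width", 4000) / res
        h = kwargs.get("height", 1800) / res
        return (w, h), res
    return (kwargs.get("width", 10), kwargs.get("height", 8)), 100


def _genome_axis(intervals: Sequence[tuple[str, int, int]]):
    """Cumulative x coordinates and chromosome boundaries."""
    offsets: dict[str, int] = {}
    cursor = 0
    for chrom, s, e in intervals:
        if chrom not in offsets:
            offsets[chrom] = cursor
        cursor = max(cursor, offsets[chrom] + e)
    lefts = np.array([offsets[c] + s for c, s, e in intervals], dtype=float)
    widths = np.array([e - s for _, s, e in intervals], dtype=float)
    bounds = [(c, off) for c, off in offsets.items()]
    return lefts, widths, bounds


def plot_stacked_histogram(
    h: HistogramTable,
    tracks: Mapping[str, LineTrack] | None = None,
    path: str = "histogram.png",
    colors: Mapping | None = None,
    fmt: tuple | None = None,
    title: str | None = None,
) -> str:
    """Stacked gain/loss frequencies along the genome, with optional
    cn-LOH/LOH lines in negative ordinates."""
    colors = colors or DEFAULT_COLORS
    fmt = fmt or DEFAULT_FORMATS["hist"]
    figsize, dpi = _figsize(*fmt)
    lefts, widths, bounds = _genome_axis(h.intervals)
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    # pooled display bins: gains +1..+3 then ">= +4"; losses -1..-4
    gain_labels = [f"+{k}" for k in range(1, DISPLAY_TOP_BIN)] + [
        f">=+{DISPLAY_TOP_BIN}"
    ]
    bottom = np.zeros(len(h.intervals))
    for k, label in enumerate(gain_labels, start=1):
        if label.startswith(">="):
            vals = sum(
                (h.track(c) for c in range(DISPLAY_TOP_BIN, 7)), np.zeros(len(h.intervals))
            )
        else:
            vals = h.track(k)
        ax.bar(
            lefts, vals, width=widths, bottom=bottom, align="edge",
            color=colors.get(label, "#888888"), linewidth=0, label=label,
        )
        bottom = bottom + vals
    bottom = np.zeros(len(h.intervals))
    for k in range(1, 5):
        vals = h.track(-k)
        ax.bar(
            lefts, -vals, width=widths, bottom=bottom, align="edge",
            color=colors.get(f"-{k}", "#888888"), linewidth=0, label=f"-{k}",
        )
        bottom = bottom - vals
    for kind, tr in (tracks or {}).items():
        tl, tw, _ = _genome_axis(tr.intervals)
        xs = np.repeat(tl, 2)
        xs[1::2] += tw
        ys = np.repeat(np.asarray(tr.values, dtype=float), 2)
        ax.plot(xs, ys, color=colors.get(kind, "#000000"), linewidth=0.8, label=kind)
    for chrom, off in bounds:
        ax.axvline(off, color="#dddddd", linewidth=0.4, zorder=0)
        ax.annotate(
            chrom, (off, 1.01), xycoords=("data", "axes fraction"),
            fontsize=5, rotation=90,
        )
    ax.axhline(0, color="black", linewidth=0.6)
    ax.set_ylabel("% of cohort (gains up / losses & LOH down)")
    ax.set_xlabel("genomic position")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_hethom_histogram(
    h: HistogramTable,
    path: str = "hethom.png",
    colors: Mapping | None = None,
    fmt: tuple | None = None,
) -> str:
    """Heterozygous/homozygous stacked frequencies: gains and neutral up,
    losses down."""
    colors = colors or DEFAULT_COLORS
    fmt = fmt or DEFAULT_FORMATS["hetHom"]
    figsize, dpi = _figsize(*fmt)
    lefts, widths, bounds = _genome_axis(h.intervals)
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    up = ("het-gain", "hom-gain", "het-neutral", "hom-neutral")
    down = ("het-loss", "hom-loss")
    bottom = np.zeros(len(h.intervals))
    for cat in up:
        vals = h.track(cat)
        ax.bar(
            lefts, vals, width=widths, bottom=bottom, align="edge",
            color=colors.get(cat, "#888888"), linewidth=0, label=cat,
        )
        bottom = bottom + vals
    bottom = np.zeros(len(h.intervals))
    for cat in down:
        vals = h.track(cat)
        ax.bar(
            lefts, -vals, width=widths, bottom=bottom, align="edge",
            color=colors.get(cat, "#888888"), linewidth=0, label=cat,
        )
        bottom = bottom - vals
    for chrom, off in bounds:
        ax.axvline(off, color="#dddddd", linewidth=0.4, zorder=0)
    ax.axhline(0, color="black", linewidth=0.6)
    ax.set_ylabel("% of cohort")
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_dendrogram(
    d: Dendrogram,
    path: str = "dendrogram.png",
    feature: str | None = None,
    feature_values: Sequence | None = None,
    fmt: tuple | None = None,
) -> str:
    fmt = fmt or DEFAULT_FORMATS["dend"]
    figsize, dpi = _figsize(*fmt)
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    _scipy_dendrogram(
        d.to_linkage(), labels=list(d.labels), ax=ax, leaf_font_size=6,
        color_threshold=0, above_threshold_color="black",
    )
    if feature_values is not None:
        levels = sorted({str(v) for v in feature_values})
        cmap = plt.get_cmap("tab10")
        color_of = {lv: cmap(i % 10) for i, lv in enumerate(levels)}
        order = {lab: i for i, lab in enumerate(d.labels)}
        vals = {d.labels[i]: feature_values[k] for k, i in enumerate(d.leaf_order)}
        for tick in ax.get_xmajorticklabels():
            tick.set_color(color_of[str(vals[tick.get_text()])])
        handles = [
            plt.Line2D([], [], marker="s", linestyle="", color=color_of[lv], label=lv)
            for lv in levels
        ]
        ax.legend(handles=handles, title=feature, fontsize=6)
    ax.set_ylabel("merge height (ward.D)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_heatmap(
    layout: HeatmapLayout,
    path: str = "heatmap.pdf",
    fmt: tuple | None = None,
    cmap: str = "RdBu_r",
) -> str:
    fmt = fmt or DEFAULT_FORMATS["heat"]
    figsize, dpi = _figsize(*fmt)
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    vals = layout.values
    im = ax.imshow(vals, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_yticks(range(len(layout.row_labels)))
    ax.set_yticklabels(layout.row_labels, fontsize=4)
    ax.set_xticks([])
    if layout.feature is not None and layout.feature_values is not None:
        ax.set_title(f"feature: {layout.feature}")
    fig.colorbar(im, ax=ax, label="copy number")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
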