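"""End-to-end analysis driver.

Wires parsing -> ploidy estimation -> windowed matrices -> base-resolution
segmentation and classification -> frequency tracks -> clustering -> text
exports and plots into one output directory, with a structured (and fully
deterministic) run log.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

from . import cluster as _cluster
from . import histogram as _hist
from . import render as _render
from ._util import fmt_number
from .genome import GenomeBuild, load_build, make_windows
from .io import (
    PloidyTable,
    SegmentSet,
    export_gistic_segments,
    parse_segments,
    read_tables,
)
from .matrix import build_matrix, export_matrix, to_relative
from .ploidy import estimate_ploidies, write_ploidies
from .segments import build_segment_matrix, classify_cells, export_segment_matrix


@dataclass
class RunConfig:
    """All driver options with their defaults."""

    input_path: str
    target_dir: str
    file_type: str = "ascat"  # "ascat" | "sequenza"
    ref_build: str = "hg19"
    build: GenomeBuild | None = None  # overrides ref_build when set
    window_size: int | None = 2_000_000
    percent: float | None = None
    ploidy_file: str | None = None
    use_custom_ploidies: bool = True
    run_gistic: bool = False
    small_mem: bool = False  # pass-through only (external-tool memory mode)
    r_color_file: str | None = None
    output_format: str | None = None
    loh_to_plot: str = "cn-LOH"
    use_full_resolution_for_hist: bool = True
    use_relative_for_clustering: bool = False
    keep_genomic_pos: bool = False
    sample_file: str | None = None
    feature: str | None = None
    plot_all: bool = True
    exclude_samples: tuple[str, ...] = ()
    include_samples: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.window_size is not None and self.percent is not None:
            raise ValueError("window size and percent are mutually exclusive")
        if self.window_size is None and self.percent is None:
            self.window_size = 2_000_000


class _RunLog:
    def __init__(self, path: str):
        self.path = path
        self.lines: list[str] = []

    def stage(self, stage_name: str, **info):
        parts = [stage_name] + [f"{k}={v}" for k, v in sorted(info.items())]
        self.lines.append("\t".join(str(p) for p in parts))

    def write(self):
        with open(self.path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of produced artifact paths
    and key intermediate objects."""
    os.makedirs(config.target_dir, exist_ok=True)
    out = lambda name: os.path.join(config.target_dir, name)
    log = _RunLog(out("run.log"))
    artifacts: dict[str, object] = {}

    build = config.build or load_build(config.ref_build)
    log.stage("build", name=build.name, chromosomes=len(build.chromosomes))

    segs = parse_segments(config.input_path, dialect=config.file_type, build=build)
    segs = segs.filter_samples(
        exclude=config.exclude_samples, include=config.include_samples
    )
    if len(segs) == 0:
        raise ValueError("no segments left after sample filtering")
    samples = segs.samples
    log.stage(
        "parse", dialect=config.file_type, segments=len(segs), samples=len(samples)
    )

    sample_table, user_ploidies = read_tables(
        config.sample_file, config.ploidy_file, samples=samples
    )
    if config.use_custom_ploidies or user_ploidies is None:
        ploidies = estimate_ploidies(segs, build, user_ploidies=user_ploidies)
    else:
        missing = [s for s in samples if s not in user_ploidies]
        if missing:
            est = estimate_ploidies(segs, build)
            user_ploidies = est.updated(user_ploidies)
        ploidies = PloidyTable({s: user_ploidies[s] for s in samples})
    write_ploidies(ploidies, out("ploidies.tsv"))
    log.stage(
        "ploidy",
        samples=len(ploidies),
        source="estimated" if config.use_custom_ploidies else "user",
    )

    windows = make_windows(build, size=config.window_size, percent=config.percent)
    m_abs = build_matrix(segs, windows, ploidies=ploidies)
    m_rel = to_relative(m_abs, ploidies)
    export_matrix(m_abs, out("matrix_absolute.tsv"))
    export_matrix(m_rel, out("matrix_relative.tsv"))
    log.stage(
        "matrix",
        windows=len(windows),
        window_size=config.window_size or f"{config.percent}%",
    )

    ms = build_segment_matrix(segs)
    ms = classify_cells(ms, ploidies)
    export_segment_matrix(ms, out("segment_matrix.tsv"))
    log.stage("segments", intervals=len(ms.intervals))

    if config.use_full_resolution_for_hist:
        hist = _hist.compute_stacked_frequencies(ms)
    else:
        hist = _hist.compute_stacked_frequencies(m_rel)
    tracks = _hist.compute_loh_tracks(ms, mode=config.loh_to_plot)
    hethom = _hist.compute_hethom_frequencies(ms)
    _hist.export_event_text(hist, out("events.tsv"))
    _hist.export_event_text(hethom, out("hethom.tsv"))
    _hist.export_loh_tracks(tracks, out("loh_tracks.tsv"))
    log.stage(
        "histogram",
        resolution="full" if config.use_full_resolution_for_hist else "windowed",
        loh=config.loh_to_plot,
        intervals=len(hist.intervals),
    )

    m_clust = m_rel if config.use_relative_for_clustering else m_abs
    dend = _cluster.ward_linkage(m_clust, on="rows")
    with open(out("dendrogram.nwk"), "w") as fh:
        fh.write(dend.to_newick() + "\n")
    layouts = _cluster.build_heatmap(
        m_clust,
        sample_table=sample_table,
        feature=config.feature,
        cluster_windows=not config.keep_genomic_pos,
    )
    if not isinstance(layouts, list):
        layouts = [layouts]
    log.stage(
        "clustering",
        flavor=m_clust.flavor,
        cluster_windows=int(not config.keep_genomic_pos),
        heatmaps=len(layouts),
    )

    if config.run_gistic:
        export_gistic_segments(segs, out("gistic_input.seg"))
        log.stage(
            "gistic",
            note="input file exported; the external GISTIC tool is not bundled",
        )

    if config.plot_all:
        colors = (
            _render.read_color_file(config.r_color_file)
            if config.r_color_file
            else _render.DEFAULT_COLORS
        )
        formats = _render.parse_output_format(config.output_format)
        fmt = formats["hist"]
        _render.plot_stacked_histogram(
            hist, tracks, out(f"histogram.{fmt[0]}"), colors=colors, fmt=fmt
        )
        fmt = formats["hetHom"]
        _render.plot_hethom_histogram(
            hethom, out(f"hethom.{fmt[0]}"), colors=colors, fmt=fmt
        )
        fmt = formats["dend"]
        if sample_table is not None and sample_table.features:
            feats = (
                [config.feature] if config.feature else sample_table.features
            )
            for feat in feats:
                fv = sample_table.values_for(
                    feat, [dend.labels[i] for i in dend.leaf_order]
                )
                _render.plot_dendrogram(
                    dend,
                    out(f"dendrogram_{feat}.{fmt[0]}"),
                    feature=feat,
                    feature_values=fv,
                    fmt=fmt,
                )
        else:
            _render.plot_dendrogram(dend, out(f"dendrogram.{fmt[0]}"), fmt=fmt)
        fmt = formats["heat"]
        for layout in layouts:
            suffix = f"_{layout.feature}" if layout.feature else ""
            _render.plot_heatmap(layout, out(f"heatmap{suffix}.{fmt[0]}"), fmt=fmt)
        log.stage("plots", formats=";".join(f"{k}:{v[0]}" for k, v in formats.items()))

    log.write()
    artifacts.update(
        segs=segs,
        ploidies=ploidies,
        windows=windows,
        matrix_absolute=m_abs,
        matrix_relative=m_rel,
        segment_matrix=ms,
        histogram=hist,
        hethom=hethom,
        loh_tracks=tracks,
        dendrogram=dend,
        target_dir=config.target_dir,
    )
    return artifacts
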