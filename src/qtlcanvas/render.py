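"""Three-panel QTL coverage figure assembly.

Panel A: mean normalised read coverage per genotype class of the lead
variant. Panel B: per-exon effect sizes with 95% CIs, significant exons
emphasised in dark blue. Panel C: transcript/event structures. All three
share one intron-compressed x-axis built on the union of the displayed
exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .coords import (
    CoordinateMap,
    CoordinateError,
    GenomicInterval,
    TranscriptModel,
    build_coordinate_map,
    map_interval,
    union_exons as merge_union_exons,
)
from .coverage import GenotypeGroupCoverage
from .io_formats import parse_variant_id
from .traits import ExonEffect


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class FigureStyle:
    """Centralised styling constants for the static figure."""

    width_in: float = 8.0
    coverage_panel_height_in: float = 1.1
    effects_panel_height_in: float = 1.6
    transcripts_row_height_in: float = 0.35
    coverage_color: str = "#5B9BD5"
    sig_color: str = "#1F3B70"  # dark blue: FDR-significant effects
    nonsig_color: str = "#9DB8D9"
    exon_color: str = "#333333"
    intron_color: str = "#999999"
    dpi: int = 100
    svg_hashsalt: str = "qtlcanvas"


DEFAULT_STYLE = FigureStyle()


def genotype_label(variant_id: str, genotype_class: int, n: int) -> str:
    """Human-readable class label, e.g. ``G/A (n=42)`` for class 1."""
    _, _, ref, alt = parse_variant_id(variant_id)
    pair = {0: f"{ref}/{ref}", 1: f"{ref}/{alt}", 2: f"{alt}/{alt}"}[genotype_class]
    return f"{pair} (n={n})"


@dataclass
class PanelBundle:
    """Everything the renderer needs, already in display coordinates."""

    cmap: CoordinateMap
    coverage_panels: list[tuple[str, GenotypeGroupCoverage]]
    effects: list[tuple[ExonEffect, float, float]]  # effect, display start/end
    transcripts: list[tuple[str, list[tuple[float, float]]]]
    variant_label: str

    def __post_init__(self) -> None:
        total = self.cmap.total_display_length
        for _, (lo, hi) in (
            [(e.exon_id, (a, b)) for e, a, b in self.effects]
            + [(tid, seg) for tid, segs in self.transcripts for seg in segs]
        ):
            if lo < -1e-9 or hi > total + 1e-9:
                raise RenderError(
                    f"element [{lo}, {hi}] outside display range [0, {total}]"
                )


def build_panel_bundle(
    exons: list[GenomicInterval] | None,
    coverage_by_class: list[GenotypeGroupCoverage],
    effects: list[ExonEffect],
    transcripts: list[TranscriptModel],
    variant_id: str,
    intron_display_length: float = 50,
) -> PanelBundle:
    """Assemble the shared-axis bundle from genomic-coordinate inputs.

    When ``exons`` is None the axis is built on the union of the
    transcripts' exons, so every panel shares identical coordinates.
    """
    if exons is None:
        if not transcripts:
            raise RenderError("need exons or transcripts to define the axis")
        exons = merge_union_exons(transcripts)
    cmap = build_coordinate_map(exons, intron_display_length)
    region = cmap.region

    if coverage_by_class:
        n_bins = len(coverage_by_class[0].mean_values)
        # coverage grids are defined over the gene region; a shorter grid
        # means the tracks do not cover the exon union
        if n_bins < 1:
            raise RenderError("empty coverage grid")

    mapped_effects = []
    for eff in effects:
        iv = eff.exon_interval
        if iv.start < region.start or iv.end > region.end:
            raise CoordinateError(
                f"effect exon {eff.exon_id} outside coverage region"
            )
        mapped_effects.append((eff, *map_interval(cmap, iv)))

    mapped_tx = []
    for t in transcripts:
        segs = [map_interval(cmap, e) for e in t.exons]
        mapped_tx.append((t.transcript_id, segs))

    panels = [
        (genotype_label(variant_id, g.genotype_class, g.n_samples), g)
        for g in coverage_by_class
    ]
    return PanelBundle(cmap, panels, mapped_effects, mapped_tx, variant_id)


def _display_grid(cmap: CoordinateMap, n_bins: int, region_len: int) -> np.ndarray:
    """Display x-coordinate of each coverage bin centre."""
    from .coords import map_position

    region = cmap.region
    bin_size = region_len / n_bins
    centres = region.start + (np.arange(n_bins) + 0.5) * bin_size
    return np.array([map_position(cmap, min(c, region.end)) for c in centres])


def render_figure(
    bundle: PanelBundle,
    out_path: str | Path,
    format: str = "svg",
    style: FigureStyle = DEFAULT_STYLE,
) -> Path:
    """Render the bundle to SVG or PNG; byte-stable for identical inputs."""
    if format not in ("svg", "png"):
        raise RenderError(f"unknown format {format!r}")
    out_path = Path(out_path)

    n_cov = max(len(bundle.coverage_panels), 1)
    n_tx = max(len(bundle.transcripts), 1)
    heights = (
        [style.coverage_panel_height_in] * n_cov
        + [style.effects_panel_height_in]
        + [style.transcripts_row_height_in * n_tx]
    )
    with matplotlib.rc_context({"svg.hashsalt": style.svg_hashsalt}):
        fig, axes = plt.subplots(
            len(heights), 1,
            figsize=(style.width_in, sum(heights) + 0.8),
            gridspec_kw={"height_ratios": heights},
            sharex=True,
        )
        axes = np.atleast_1d(axes)
        total = bundle.cmap.total_display_length
        region_len = len(bundle.cmap.region)

        cov_axes, eff_ax, tx_ax = axes[:n_cov], axes[n_cov], axes[n_cov + 1]
        ymax = max(
            (g.mean_values.max() for _, g in bundle.coverage_panels), default=1.0
        ) or 1.0
        for ax, (label, g) in zip(cov_axes, bundle.coverage_panels or []):
            x = _display_grid(bundle.cmap, len(g.mean_values), region_len)
            ax.fill_between(x, g.mean_values, step="mid", color=style.coverage_color)
            ax.set_ylim(0, ymax * 1.05)
            ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=8)
            ax.set_yticks([])
        if not bundle.coverage_panels:
            cov_axes[0].text(0.5, 0.5, "no coverage", transform=cov_axes[0].transAxes,
                             ha="center", fontsize=8)
            cov_axes[0].set_yticks([])
        cov_axes[0].set_title(
            f"Read coverage stratified by {bundle.variant_label}", fontsize=9
        )

        if bundle.effects:
            for eff, lo, hi in bundle.effects:
                mid = (lo + hi) / 2
                color = style.sig_color if eff.fdr_significant else style.nonsig_color
                eff_ax.errorbar(
                    mid, eff.beta,
                    yerr=[[eff.beta - eff.ci_low], [eff.ci_high - eff.beta]],
                    fmt="o", color=color, markersize=4, capsize=2,
                )
            eff_ax.axhline(0, color="#CCCCCC", lw=0.8, zorder=0)
        else:
            eff_ax.text(0.5, 0.5, "no exon effects", transform=eff_ax.transAxes,
                        ha="center", fontsize=8)
        eff_ax.set_ylabel("beta (95% CI)", fontsize=8)

        for row, (tid, segs) in enumerate(bundle.transcripts):
            y = -row
            lo_all = min(s[0] for s in segs)
            hi_all = max(s[1] for s in segs)
            tx_ax.hlines(y, lo_all, hi_all, color=style.intron_color, lw=1)
            for lo, hi in segs:
                tx_ax.add_patch(
                    plt.Rectangle((lo, y - 0.25), hi - lo, 0.5,
                                  color=style.exon_color, lw=0)
                )
            tx_ax.text(-total * 0.01, y, tid, ha="right", va="center", fontsize=7)
        tx_ax.set_ylim(-len(bundle.transcripts) + 0.5, 0.6)
        tx_ax.set_yticks([])
        tx_ax.set_xlim(-total * 0.12, total * 1.02)
        tx_ax.set_xlabel("display position (introns compressed)", fontsize=8)

        fig.align_ylabels()
        fig.savefig(
            out_path, format=format, dpi=style.dpi,
            metadata={"Date": None} if format == "svg" else None,
        )
        plt.close(fig)
    return out_path


def bundle_geometry_tsv(bundle: PanelBundle) -> str:
    """TSV dump of all drawable geometry, for headless testing."""
    lines = ["panel\telement\tx0\tx1\tvalue\tflag"]
    for label, g in bundle.coverage_panels:
        lines.append(
            f"coverage\t{label}\t0\t{bundle.cmap.total_display_length:g}"
            f"\t{g.mean_values.mean():.6g}\tn={g.n_samples}"
        )
    for eff, lo, hi in bundle.effects:
        lines.append(
            f"effects\t{eff.exon_id}\t{lo:g}\t{hi:g}\t{eff.beta:.6g}"
            f"\t{'sig' if eff.fdr_significant else 'ns'}"
        )
    for tid, segs in bundle.transcripts:
        for lo, hi in segs:
            lines.append(f"transcripts\t{tid}\t{lo:g}\t{hi:g}\t\t")
    return "\n".join(lines) + "\n"
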