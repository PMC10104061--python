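"""Intron-compressing coordinate transform for gene-region display.

Gene regions are mostly intron: drawn to genomic scale, exonic read-coverage
variation is invisible. The transform used here keeps every exon at its true
length and linearly squeezes each intervening intron onto a fixed display
width (50 nt by default), giving a piecewise-linear, monotone genomic ->
display mapping shared by every panel of a figure.

All coordinates are 0-based half-open. GFF3's 1-based inclusive convention
is converted at parse time in :mod:`qtlcanvas.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

DEFAULT_INTRON_DISPLAY_LENGTH = 50


class CoordinateError(ValueError):
    """Structural problem with intervals or an out-of-range position."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise CoordinateError(
                f"end must exceed start: [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and (
            self.start < other.end and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript as an ordered list of exons on a single chrom/strand."""

    gene_id: str
    transcript_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise CoordinateError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise CoordinateError(
                f"{self.transcript_id}: exons on multiple chromosomes {sorted(chroms)}"
            )
        _check_sorted_disjoint(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class Segment:
    """One linear piece of the map: genomic interval, display offset, scale."""

    genomic: GenomicInterval
    display_start: float
    scale: float  # display units per genomic bp; 1.0 for exons

    @property
    def display_end(self) -> float:
        return self.display_start + len(self.genomic) * self.scale

    @property
    def is_exonic(self) -> bool:
        return self.scale == 1.0


@dataclass(frozen=True)
class CoordinateMap:
    """Piecewise-linear genomic -> display transform over a gene region."""

    segments: tuple[Segment, ...]
    intron_display_length: float
    total_display_length: float

    @property
    def region(self) -> GenomicInterval:
        first, last = self.segments[0].genomic, self.segments[-1].genomic
        return GenomicInterval(first.chrom, first.start, last.end)


def _check_sorted_disjoint(ivs: Sequence[GenomicInterval]) -> None:
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.start:
            raise CoordinateError(f"intervals unsorted: {a} before {b}")
        if b.start < a.end:
            raise CoordinateError(f"intervals overlap: {a} and {b}")


def union_exons(transcripts: Iterable[TranscriptModel]) -> list[GenomicInterval]:
    """Merge the exons of several transcripts into disjoint union intervals.

    The merged union defines the shared display axis when multiple
    transcripts are drawn in one figure.
    """
    exons = sorted(
        (e for t in transcripts for e in t.exons), key=lambda e: (e.start, e.end)
    )
    if not exons:
        raise CoordinateError("no exons to merge")
    merged: list[GenomicInterval] = []
    cur_start, cur_end = exons[0].start, exons[0].end
    chrom = exons[0].chrom
    for e in exons[1:]:
        if e.chrom != chrom:
            raise CoordinateError("exons span multiple chromosomes")
        if e.start <= cur_end:
            cur_end = max(cur_end, e.end)
        else:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
            cur_start, cur_end = e.start, e.end
    merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def build_coordinate_map(
    union_exons: Sequence[GenomicInterval],
    intron_display_length: float = DEFAULT_INTRON_DISPLAY_LENGTH,
) -> CoordinateMap:
    """Build the transform from non-overlapping sorted exon intervals.

    Exons map length-preservingly (scale 1); each gap between consecutive
    exons maps linearly onto exactly ``intron_display_length`` display units.
    Zero-length gaps (book-ended exons) are treated as contiguous sequence
    and contribute no intron segment.
    """
    if not union_exons:
        raise CoordinateError("empty exon list")
    if intron_display_length < 1:
        raise CoordinateError(
            f"intron_display_length must be >= 1, got {intron_display_length}"
        )
    _check_sorted_disjoint(union_exons)
    chrom = union_exons[0].chrom
    if any(e.chrom != chrom for e in union_exons):
        raise CoordinateError("exons on multiple chromosomes")

    segments: list[Segment] = []
    offset = 0.0
    prev: GenomicInterval | None = None
    for exon in union_exons:
        if prev is not None and exon.start > prev.end:
            gap = GenomicInterval(chrom, prev.end, exon.start)
            segments.append(
                Segment(gap, offset, intron_display_length / len(gap))
            )
            offset += intron_display_length
        segments.append(Segment(exon, offset, 1.0))
        offset += len(exon)
        prev = exon
    return CoordinateMap(
        segments=tuple(segments),
        intron_display_length=intron_display_length,
        total_display_length=offset,
    )


def map_position(cmap: CoordinateMap, pos: float) -> float:
    """Map a genomic position to display units (monotone non-decreasing)."""
    region = cmap.region
    if not (region.start <= pos <= region.end):
        raise CoordinateError(
            f"position {pos} outside region [{region.start}, {region.end}]"
        )
    for seg in cmap.segments:
        if seg.genomic.start <= pos < seg.genomic.end:
            return seg.display_start + (pos - seg.genomic.start) * seg.scale
    # pos == region.end
    return cmap.total_display_length


def map_interval(
    cmap: CoordinateMap, iv: GenomicInterval
) -> tuple[float, float]:
    """Map a genomic interval to a display (start, end) pair."""
    return map_position(cmap, iv.start), map_position(cmap, iv.end)


def invert_position(cmap: CoordinateMap, display_pos: float) -> float:
    """Inverse transform; exact for positions that land inside exons."""
    if not (0 <= display_pos <= cmap.total_display_length):
        raise CoordinateError(
            f"display position {display_pos} outside [0, {cmap.total_display_length}]"
        )
    for seg in cmap.segments:
        if seg.display_start <= display_pos < seg.display_end:
            return seg.genomic.start + (display_pos - seg.display_start) / seg.scale
    return float(cmap.region.end)


def map_to_tsv(cmap: CoordinateMap) -> str:
    """Serialise the segment table to TSV (debugging aid)."""
    lines = ["chrom\tstart\tend\tdisplay_start\tdisplay_end\tscale\tkind"]
    for seg in cmap.segments:
        g = seg.genomic
        kind = "exon" if seg.is_exonic else "intron"
        lines.append(
            f"{g.chrom}\t{g.start}\t{g.end}\t{seg.display_start:g}"
            f"\t{seg.display_end:g}\t{seg.scale:.10g}\t{kind}"
        )
    return "\n".join(lines) + "\n"
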