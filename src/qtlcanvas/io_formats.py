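"""Readers and writers for the standard formats the toolkit touches.

GFF3 exon annotation (via gffutils), VCF genotype dosages (via pysam),
bigWig/bedGraph coverage (via pyBigWig / text parsing), and tabix-indexed
TSV summary statistics (via bgzip + pysam.TabixFile). Also houses the chrX
conventions: GRCh38 pseudoautosomal regions and the rule that male dosages
outside the PARs are doubled onto the female 0-2 scale.

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
inclusive and VCF's 1-based positions are converted at the boundary.
Variant IDs use the canonical underscore form chr_pos_ref_alt with a
1-based position (e.g. ``chr11_14855172_G_A``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam

from .coords import GenomicInterval, TranscriptModel
from .coverage import CoverageTrack

logger = logging.getLogger(__name__)

# GRCh38 pseudoautosomal regions on chrX (0-based half-open)
PAR1_GRCH38 = GenomicInterval("chrX", 10_000, 2_781_479)
PAR2_GRCH38 = GenomicInterval("chrX", 155_701_382, 156_030_895)
DEFAULT_PAR_REGIONS = (PAR1_GRCH38, PAR2_GRCH38)

SUMSTATS_COLUMNS = [
    "chrom", "pos", "variant_id", "trait_id", "group_id", "beta", "se", "p",
]


class FormatError(ValueError):
    pass


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant ID, pos 1-based."""
    return f"{chrom}_{pos}_{ref}_{alt}"


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    parts = variant_id.rsplit("_", 3)
    if len(parts) != 4:
        raise FormatError(f"malformed variant ID {variant_id!r}")
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


@dataclass
class DosageTable:
    """Per-sample alternative-allele dosages for one variant."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosages: dict[str, float | None]

    def __post_init__(self) -> None:
        expected = make_variant_id(self.chrom, self.pos, self.ref, self.alt)
        if self.variant_id != expected:
            raise FormatError(
                f"variant_id {self.variant_id!r} inconsistent with fields "
                f"({expected!r})"
            )
        for s, d in self.dosages.items():
            if d is not None and not (-1e-6 <= d <= 2 + 1e-6):
                raise FormatError(f"{s}: dosage {d} outside [0, 2]")


# ---------------------------------------------------------------------------
# GFF3


def read_exons_gff3(path: str | Path, gene_id: str) -> list[TranscriptModel]:
    """Read a gene's transcripts (as exon lists) from GFF3.

    Exon features are grouped by their parent transcript, converted from
    1-based inclusive to 0-based half-open, and sorted by start.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"failed to parse GFF3 {path}: {exc}") from exc

    models: list[TranscriptModel] = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        parents = feat.attributes.get("Parent", [])
        if gene_id not in parents and feat.attributes.get("gene_id", [None])[0] != gene_id:
            continue
        exons = []
        for ex in db.children(feat, featuretype="exon", order_by="start"):
            exons.append(
                GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand or ".")
            )
        if exons:
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=feat.id,
                    exons=tuple(sorted(exons, key=lambda e: e.start)),
                )
            )
    if not models:
        raise FormatError(f"gene {gene_id!r} not found in {path}")
    return models


def write_gff3(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as a minimal GFF3 (gene/transcript/exon features)."""
    lines = ["##gff-version 3"]
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    for gene_id, txs in genes.items():
        start = min(t.span.start for t in txs) + 1
        end = max(t.span.end for t in txs)
        chrom, strand = txs[0].chrom, txs[0].strand or "."
        lines.append(
            f"{chrom}\t.\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in txs:
            lines.append(
                f"{chrom}\t.\ttranscript\t{t.span.start + 1}\t{t.span.end}\t."
                f"\t{strand}\t.\tID={t.transcript_id};Parent={gene_id}"
            )
            for i, e in enumerate(t.exons, 1):
                lines.append(
                    f"{chrom}\t.\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t."
                    f"\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF dosages


def read_dosages_vcf(path: str | Path, variant_id: str) -> DosageTable:
    """Extract one variant's per-sample dosages from a VCF.

    The FORMAT/DS field is used when present; otherwise the dosage is the
    alternative-allele count of the GT call. Missing GT yields a missing
    dosage.
    """
    chrom, pos, ref, alt = parse_variant_id(variant_id)
    vf = pysam.VariantFile(str(path))
    try:
        records = vf.fetch(chrom, pos - 1, pos)
    except ValueError:
        records = (r for r in vf.fetch() if r.chrom == chrom and r.pos == pos)
    for rec in records:
        if rec.pos != pos or rec.ref != ref:
            continue
        alts = rec.alts or ()
        if alt not in alts:
            if len(alts) > 1:
                raise FormatError(
                    f"multiallelic record at {chrom}:{pos} lacks alt {alt!r}"
                )
            continue
        alt_index = alts.index(alt) + 1
        dosages: dict[str, float | None] = {}
        for sample, call in rec.samples.items():
            ds = call.get("DS")
            if ds is not None:
                dosages[sample] = float(ds if not isinstance(ds, tuple) else ds[0])
                continue
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                dosages[sample] = None
            else:
                dosages[sample] = float(sum(1 for a in gt if a == alt_index))
        return DosageTable(variant_id, chrom, pos, ref, alt, dosages)
    raise FormatError(f"variant {variant_id} not found in {path}")


def write_vcf(
    variants: list[tuple[str, int, str, str]],
    sample_ids: list[str],
    genotypes: np.ndarray,
    path: str | Path,
) -> None:
    """Write hard-call genotypes (0/1/2 alt counts) as an uncompressed VCF.

    ``genotypes`` is variants x samples; values may be NaN for missing.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = sorted({v[0] for v in variants})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    order = sorted(range(len(variants)), key=lambda i: (variants[i][0], variants[i][1]))
    for i in order:
        chrom, pos, ref, alt = variants[i]
        vid = make_variant_id(chrom, pos, ref, alt)
        calls = [
            "./." if math.isnan(g) else gt_strings[int(round(g))]
            for g in genotypes[i]
        ]
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def adjust_male_nonpar_dosage(
    dt: DosageTable,
    sex: dict[str, str],
    par_regions: tuple[GenomicInterval, ...] = DEFAULT_PAR_REGIONS,
) -> DosageTable:
    """Double male dosages for chrX variants outside the PARs.

    Hemizygous male genotypes are called on a 0-1 scale; doubling puts them
    on the female 0-2 scale. Dosages inside a PAR, female samples, and
    samples of unknown sex (warned) are unchanged. Doubled values exceeding
    2 are clipped with a warning.
    """
    pos0 = dt.pos - 1
    in_par = any(
        p.chrom == dt.chrom and p.contains(pos0) for p in par_regions
    )
    if in_par:
        return dt
    out: dict[str, float | None] = {}
    for sample, d in dt.dosages.items():
        s = sex.get(sample)
        if s is None:
            logger.warning("unknown sex for sample %s; dosage unchanged", sample)
            out[sample] = d
        elif s == "male" and d is not None:
            doubled = d * 2
            if doubled > 2:
                logger.warning(
                    "%s: doubled dosage %.3f > 2, clipping", sample, doubled
                )
                doubled = 2.0
            out[sample] = doubled
        else:
            out[sample] = d
    return DosageTable(dt.variant_id, dt.chrom, dt.pos, dt.ref, dt.alt, out)


# ---------------------------------------------------------------------------
# Coverage tracks


def read_coverage_track(
    path: str | Path, region: GenomicInterval, sample_id: str | None = None
) -> CoverageTrack:
    """Read base-resolution coverage over a region from bigWig or bedGraph.

    Bases not covered by any record are 0. The format is chosen by file
    extension (.bw/.bigwig vs anything else as bedGraph).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if path.suffix.lower() in (".bw", ".bigwig"):
        values = _read_bigwig(path, region)
    else:
        values = _read_bedgraph(path, region)
    return CoverageTrack(sample_id, region, values, bin_size=1)


def _read_bigwig(path: Path, region: GenomicInterval) -> np.ndarray:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if region.chrom not in bw.chroms():
            raise FormatError(
                f"contig {region.chrom!r} not in {path} "
                f"(available: {sorted(bw.chroms())})"
            )
        vals = bw.values(region.chrom, region.start, region.end, numpy=True)
    finally:
        bw.close()
    return np.nan_to_num(np.asarray(vals, dtype=float))


def _read_bedgraph(path: Path, region: GenomicInterval) -> np.ndarray:
    values = np.zeros(len(region))
    seen_contigs: set[str] = set()
    hit = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            seen_contigs.add(chrom)
            if chrom != region.chrom:
                continue
            hit = True
            lo = max(start, region.start) - region.start
            hi = min(end, region.end) - region.start
            if hi > lo:
                values[lo:hi] = depth
    if not hit and region.chrom not in seen_contigs and seen_contigs:
        raise FormatError(
            f"contig {region.chrom!r} not in {path} "
            f"(available: {sorted(seen_contigs)})"
        )
    return values


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as 4-column bedGraph, merging equal-depth runs."""
    if track.bin_size != 1:
        raise FormatError("bedGraph writer expects base-resolution tracks")
    r = track.region
    lines = []
    vals = track.values
    i = 0
    while i < len(vals):
        j = i
        while j < len(vals) and vals[j] == vals[i]:
            j += 1
        if vals[i] != 0:
            lines.append(f"{r.chrom}\t{r.start + i}\t{r.start + j}\t{vals[i]:g}")
        i = j
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Tabix-indexed summary statistics


def write_sumstats(df: pd.DataFrame, path: str | Path) -> Path:
    """Write summary statistics as bgzip-compressed, tabix-indexed TSV.

    Rows are coordinate-sorted (with a notice if the input was not); the
    header line starts with ``#`` so tabix skips it. Returns the .gz path.
    """
    missing = [c for c in ("chrom", "pos") if c not in df.columns]
    if missing:
        raise FormatError(f"summary stats lack columns {missing}")
    if not df[["chrom", "pos"]].equals(
        df[["chrom", "pos"]].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    ):
        logger.info("summary stats unsorted; sorting before write")
    df = df.sort_values(["chrom", "pos"], kind="stable")
    path = Path(path)
    plain = path.with_suffix("") if path.suffix == ".gz" else path
    header = "#" + "\t".join(df.columns)
    body = df.to_csv(sep="\t", header=False, index=False)
    plain.write_text(header + "\n" + body)
    gz = pysam.tabix_index(
        str(plain), seq_col=0, start_col=1, end_col=1, meta_char="#",
        force=True, keep_original=False,
    )
    return Path(gz)


def read_sumstats(
    path: str | Path, region: GenomicInterval | None = None
) -> pd.DataFrame:
    """Read a (region of a) tabix-indexed summary-statistics TSV."""
    tbx = pysam.TabixFile(str(path))
    try:
        columns = tbx.header[0].lstrip("#").split("\t")
        if region is None:
            rows = [r.split("\t") for contig in tbx.contigs for r in tbx.fetch(contig)]
        else:
            try:
                rows = [
                    r.split("\t")
                    for r in tbx.fetch(region.chrom, region.start, region.end)
                ]
            except ValueError:
                rows = []
    finally:
        tbx.close()
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        if col not in ("chrom", "variant_id", "trait_id", "group_id", "cs_id"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(int)
    return df
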