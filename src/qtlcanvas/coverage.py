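"""Per-sample read-coverage handling and genotype stratification.

A coverage track is a vector of depths over a gene region at base or binned
resolution. Tracks are binned (mean depth per bin), normalised to depth per
million library reads, and averaged within genotype classes of a lead
variant (0/1/2 alternative-allele copies) to produce the stratified panels
of a QTL coverage plot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .coords import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 5  # bp, the bamCoverage convention used upstream

DOSAGE_TOL = 1e-6


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageTrack:
    """Depth over one region for one sample, at ``bin_size`` resolution.

    The final bin may be partial; its value is the mean over its true width.
    """

    sample_id: str
    region: GenomicInterval
    values: np.ndarray
    bin_size: int = 1

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        expected = math.ceil(len(self.region) / self.bin_size)
        if len(vals) != expected:
            raise CoverageError(
                f"{self.sample_id}: {len(vals)} values for region of "
                f"{len(self.region)} bp at bin size {self.bin_size} "
                f"(expected {expected})"
            )
        if np.any(vals < 0):
            raise CoverageError(f"{self.sample_id}: negative depth values")

    def same_grid(self, other: "CoverageTrack") -> bool:
        r, o = self.region, other.region
        return (
            r.chrom == o.chrom
            and r.start == o.start
            and r.end == o.end
            and self.bin_size == other.bin_size
        )


@dataclass(frozen=True)
class GenotypeGroupCoverage:
    """Mean normalised depth per bin for one genotype class."""

    genotype_class: int
    n_samples: int
    mean_values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.mean_values, dtype=float)
        object.__setattr__(self, "mean_values", vals)
        if self.n_samples < 0:
            raise CoverageError("negative sample count")
        if not np.all(np.isfinite(vals)):
            raise CoverageError("non-finite group means")


def bin_coverage(track: CoverageTrack, bin_size: int = DEFAULT_BIN_SIZE) -> CoverageTrack:
    """Re-bin a track: each output bin is the mean depth over its bases.

    Total signal (sum of value x bin width) is conserved exactly when the
    region length is divisible by ``bin_size``; the trailing partial bin is
    averaged over its true width, not padded.
    """
    if bin_size < 1:
        raise CoverageError(f"bin size must be >= 1, got {bin_size}")
    if track.bin_size != 1:
        raise CoverageError("can only re-bin base-resolution tracks")
    n = len(track.region)
    values = track.values
    n_bins = math.ceil(n / bin_size)
    out = np.empty(n_bins)
    full = n // bin_size
    if full:
        out[:full] = values[: full * bin_size].reshape(full, bin_size).mean(axis=1)
    if n_bins > full:
        out[full] = values[full * bin_size :].mean()
    return CoverageTrack(track.sample_id, track.region, out, bin_size)


def normalize_track(track: CoverageTrack, library_size: float) -> CoverageTrack:
    """Scale depth to per-million-library-reads units."""
    if library_size <= 0:
        raise CoverageError(f"library size must be positive, got {library_size}")
    return CoverageTrack(
        track.sample_id,
        track.region,
        track.values * (1e6 / library_size),
        track.bin_size,
    )


def assign_genotype_groups(
    dosages: dict[str, float | None],
    max_dosage_distance: float = 0.5,
) -> tuple[dict[str, int], int]:
    """Round dosages in [0, 2] to hard genotype classes {0, 1, 2}.

    Half-way dosages round up (0.5 -> 1). Samples whose dosage sits further
    than ``max_dosage_distance`` from the nearest integer are excluded; the
    default of 0.5 admits every in-range dosage. Returns the assignment and
    the number of samples excluded as missing or too ambiguous.
    """
    groups: dict[str, int] = {}
    n_excluded = 0
    for sample, d in dosages.items():
        if d is None or (isinstance(d, float) and math.isnan(d)):
            n_excluded += 1
            continue
        if d < -DOSAGE_TOL or d > 2 + DOSAGE_TOL:
            raise CoverageError(f"{sample}: dosage {d} outside [0, 2]")
        d = min(max(d, 0.0), 2.0)
        cls = int(math.floor(d + 0.5))  # round half up
        if abs(d - cls) > max_dosage_distance + DOSAGE_TOL:
            n_excluded += 1
            continue
        groups[sample] = cls
    if not groups and dosages:
        logger.warning("all %d samples missing or excluded", len(dosages))
    return groups, n_excluded


def group_mean_coverage(
    tracks: list[CoverageTrack],
    groups: dict[str, int],
    rescale_to_unit_max: bool = False,
) -> list[GenotypeGroupCoverage]:
    """Average normalised tracks within each genotype class, per bin.

    All tracks must share one region/bin grid; every sample in ``groups``
    must have a track. Classes with no samples are simply absent from the
    result. With ``rescale_to_unit_max`` the class means are jointly divided
    by the global maximum for a 0-1 display axis.
    """
    by_sample = {t.sample_id: t for t in tracks}
    if len(by_sample) != len(tracks):
        raise CoverageError("duplicate sample IDs among tracks")
    ref = tracks[0] if tracks else None
    for t in tracks[1:]:
        if not t.same_grid(ref):
            raise CoverageError(
                f"track grid mismatch: {t.sample_id} vs {ref.sample_id}"
            )
    members: dict[int, list[np.ndarray]] = {}
    for sample, cls in groups.items():
        if sample not in by_sample:
            raise CoverageError(f"no coverage track for grouped sample {sample}")
        members.setdefault(cls, []).append(by_sample[sample].values)

    out = []
    for cls in (0, 1, 2):
        if cls not in members:
            logger.info("genotype class %d has no samples; omitted", cls)
            continue
        stack = np.vstack(members[cls])
        out.append(GenotypeGroupCoverage(cls, stack.shape[0], stack.mean(axis=0)))
    if rescale_to_unit_max and out:
        peak = max(g.mean_values.max() for g in out)
        if peak > 0:
            out = [
                GenotypeGroupCoverage(g.genotype_class, g.n_samples, g.mean_values / peak)
                for g in out
            ]
    return out
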