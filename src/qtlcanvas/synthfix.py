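"""Seeded synthetic fixtures emulating the toolkit's upstream inputs.

Every generator is deterministic for a fixed seed and returns a "truth"
record alongside its files, so downstream assertions can be exact: HWE
genotypes at a stated allele frequency, genotype-dependent exon coverage
with count noise (a splicing-QTL archetype: one exon's inclusion
proportion shifts with dosage; an eQTL archetype multiplies the whole
gene), multi-trait credible-set structures with planted variant overlaps
and QC violations, and peaked log-Bayes-factor vectors for each
colocalisation hypothesis.

Defaults mirror the study conditions exercised throughout the test suite:
200 samples, MAF 0.3, mean exonic depth 50, effect 0.8 on the
inverse-normal scale, Poisson count noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .coloc import SignalLBF
from .coords import GenomicInterval, TranscriptModel
from .coverage import CoverageTrack
from .io_formats import DosageTable, make_variant_id, write_bedgraph, write_vcf

DEFAULT_EXON_LENGTHS = (150, 120, 90, 100, 180)
DEFAULT_INTRON_LENGTHS = (800, 1500, 600, 2000)


@dataclass
class SimConfig:
    """Shared knobs for all generators; see module docstring for defaults."""

    seed: int = 0
    n_samples: int = 200
    maf: float = 0.3
    effect_size: float = 0.8
    depth_mean: float = 50.0
    noise: str = "poisson"  # or "negbin"
    dispersion: float = 0.1
    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS
    intron_lengths: tuple[int, ...] = DEFAULT_INTRON_LENGTHS
    affected_exon_index: int = 3
    mechanism: str = "sqtl"  # "sqtl" (inclusion shift) or "eqtl" (gene-wide)
    chrom: str = "chr11"
    gene_start: int = 14_850_000
    gene_id: str = "GENE1"
    # credible-set fixture shape
    n_groups: int = 1000
    traits_per_group: int = 20
    signals_per_group: tuple[int, int] = (1, 3)
    qc_violation_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"maf {self.maf} outside (0, 0.5]")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron length per exon gap")
        if not (0 <= self.affected_exon_index < len(self.exon_lengths)):
            raise ValueError("affected exon index out of range")
        if self.noise not in ("poisson", "negbin"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed * 100_003 + salt)


def gene_model(cfg: SimConfig) -> TranscriptModel:
    """The simulated gene's exon structure as a single transcript."""
    exons = []
    pos = cfg.gene_start
    for i, length in enumerate(cfg.exon_lengths):
        exons.append(GenomicInterval(cfg.chrom, pos, pos + length, "+"))
        pos += length
        if i < len(cfg.intron_lengths):
            pos += cfg.intron_lengths[i]
    return TranscriptModel(cfg.gene_id, f"{cfg.gene_id}.t1", tuple(exons))


def sim_genotypes(cfg: SimConfig, out_vcf: str | Path | None = None) -> DosageTable:
    """Hardy-Weinberg genotypes at the configured allele frequency.

    The variant sits in the first intron of the simulated gene. Optionally
    writes a single-record VCF (byte-identical for a fixed seed).
    """
    rng = cfg.rng(salt=1)
    p = cfg.maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
    geno = rng.choice([0, 1, 2], size=cfg.n_samples, p=probs)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    model = gene_model(cfg)
    pos = model.exons[0].end + 100  # 1-based position inside intron 1
    vid = make_variant_id(cfg.chrom, pos, "G", "A")
    dt = DosageTable(
        vid, cfg.chrom, pos, "G", "A",
        {s: float(g) for s, g in zip(samples, geno)},
    )
    if out_vcf is not None:
        write_vcf(
            [(cfg.chrom, pos, "G", "A")], samples,
            geno.astype(float)[None, :], out_vcf,
        )
    return dt


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, cfg: SimConfig) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if cfg.noise == "poisson":
        return rng.poisson(mean).astype(float)
    # negative binomial with Var = mu + dispersion * mu^2
    disp = cfg.dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        n = 1.0 / disp
        p = n / (n + mean)
    out = np.where(mean > 0, rng.negative_binomial(n, np.where(mean > 0, p, 1.0)), 0)
    return out.astype(float)


@dataclass
class CoverageTruth:
    """Exact expected per-exon depths per genotype class, plus geometry."""

    exon_intervals: list[GenomicInterval]
    affected_exon_index: int
    expected_exon_depth: dict[int, list[float]]  # class -> per-exon expectation
    inclusion_by_class: dict[int, float]
    mechanism: str


def sim_coverage_dataset(
    cfg: SimConfig,
    dosages: DosageTable,
    out_dir: str | Path | None = None,
) -> tuple[list[CoverageTrack], np.ndarray, CoverageTruth]:
    """Per-sample coverage tracks with a genotype-dependent affected exon.

    Under the splicing archetype the affected exon's expected depth is
    ``depth_mean * sigmoid(effect_size * (dosage - 1))`` — inclusion 0.5 for
    heterozygotes, shifted up/down with allele count — while other exons sit
    at ``depth_mean``. The eQTL archetype multiplies every exon by
    ``exp(0.2 * effect_size * dosage)`` instead. Introns have depth 0.
    Counts are drawn per base under the configured noise model.

    Returns (base-resolution tracks, exon-mean matrix [exon x sample], truth).
    Optionally writes one bedGraph per sample into ``out_dir``.
    """
    rng = cfg.rng(salt=2)
    model = gene_model(cfg)
    region = model.span
    exons = list(model.exons)
    samples = sorted(dosages.dosages)
    n_exons = len(exons)

    tracks: list[CoverageTrack] = []
    exon_means = np.zeros((n_exons, len(samples)))
    for si, sample in enumerate(samples):
        d = dosages.dosages[sample]
        d = 0.0 if d is None else d
        values = np.zeros(len(region))
        for ei, exon in enumerate(exons):
            mu = _expected_exon_depth(cfg, ei, d)
            lo, hi = exon.start - region.start, exon.end - region.start
            counts = _draw_counts(rng, np.full(hi - lo, mu), cfg)
            values[lo:hi] = counts
            exon_means[ei, si] = counts.mean()
        track = CoverageTrack(sample, region, values, bin_size=1)
        tracks.append(track)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_bedgraph(track, out_dir / f"{sample}.bedgraph")

    truth = CoverageTruth(
        exon_intervals=exons,
        affected_exon_index=cfg.affected_exon_index,
        expected_exon_depth={
            g: [_expected_exon_depth(cfg, ei, g) for ei in range(n_exons)]
            for g in (0, 1, 2)
        },
        inclusion_by_class={
            g: float(expit(cfg.effect_size * (g - 1))) for g in (0, 1, 2)
        },
        mechanism=cfg.mechanism,
    )
    return tracks, exon_means, truth


def _expected_exon_depth(cfg: SimConfig, exon_index: int, dosage: float) -> float:
    if cfg.mechanism == "eqtl":
        return cfg.depth_mean * float(np.exp(0.2 * cfg.effect_size * dosage))
    if exon_index == cfg.affected_exon_index:
        return cfg.depth_mean * float(expit(cfg.effect_size * (dosage - 1)))
    return cfg.depth_mean


def sim_exon_phenotypes(
    cfg: SimConfig, dosages: DosageTable, n_exons: int | None = None
) -> tuple[np.ndarray, list[str], int]:
    """Latent exon phenotypes with the effect planted at one exon.

    The affected exon's value is ``effect_size * dosage + N(0, 1)`` on the
    latent scale the inverse normal transform recovers; other exons are pure
    noise. Returns (exon x sample matrix, exon IDs, affected index).
    """
    rng = cfg.rng(salt=3)
    if n_exons is None:
        n_exons = len(cfg.exon_lengths)
    samples = sorted(dosages.dosages)
    d = np.array([dosages.dosages[s] or 0.0 for s in samples])
    Y = rng.standard_normal((n_exons, len(samples)))
    Y[cfg.affected_exon_index] += cfg.effect_size * d
    ids = [f"{cfg.gene_id}.e{i + 1}" for i in range(n_exons)]
    return Y, ids, cfg.affected_exon_index


@dataclass
class CredibleSetTruth:
    """Planted outcome of the filtering pipeline."""

    expected_selected: dict[str, str]  # "<group>:<signal>" -> best trait_id
    n_qc_violating: int
    n_sets: int


def sim_credible_sets(
    cfg: SimConfig, out_tsv: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, CredibleSetTruth]:
    """Credible-set table + matching summary statistics + planted truth.

    Per group, 1-3 latent causal variants (signals); each signal spawns
    credible sets for 2-4 traits, all containing the causal variant so they
    form one connected component. The planted best trait carries PIP 0.95
    at the causal variant; every other set's PIPs stay below 0.8. A known
    fraction of extra sets violates QC (low z or >200 variants) and must be
    dropped without changing any selection. Summary statistics carry one
    row per trait per cis variant.

    Returns (credible-set long table, summary-stat table, truth).
    """
    rng = cfg.rng(salt=4)
    cs_rows: list[tuple] = []
    stat_rows: list[tuple] = []
    expected: dict[str, str] = {}
    n_violating = 0
    n_sets = 0
    lo, hi = cfg.signals_per_group

    for gi in range(cfg.n_groups):
        group = f"G{gi:05d}"
        traits = [f"{group}.T{t:02d}" for t in range(cfg.traits_per_group)]
        chrom = f"chr{1 + gi % 22}"
        base_pos = 1_000_000 + gi * 10_000
        n_signals = int(rng.integers(lo, hi + 1))
        for si in range(n_signals):
            sig_pos = base_pos + si * 1_000
            pool = [
                make_variant_id(chrom, sig_pos + k, "A", "G") for k in range(12)
            ]
            causal = pool[0]
            n_traits_with_sets = int(rng.integers(2, 5))
            member_traits = list(
                rng.choice(traits, size=n_traits_with_sets, replace=False)
            )
            best = member_traits[int(rng.integers(n_traits_with_sets))]
            expected[f"{group}:s{si}"] = best
            for trait in member_traits:
                cs_id = f"{trait}_L{si + 1}"
                size = int(rng.integers(1, 8))
                variants = [causal] + list(
                    rng.choice(pool[1:], size=size, replace=False)
                )
                peak_pip = 0.95 if trait == best else float(rng.uniform(0.2, 0.8))
                zpeak = float(rng.uniform(4, 12))
                for vi, v in enumerate(variants):
                    pip = peak_pip if vi == 0 else float(
                        rng.uniform(0, min(0.15, peak_pip / 4))
                    )
                    z = zpeak if vi == 0 else float(rng.uniform(-3, 3))
                    cs_rows.append((cs_id, trait, group, si + 1, v, pip, z))
                n_sets += 1
            # QC-violating extras, never owned by the best trait's set
            if rng.uniform() < cfg.qc_violation_rate * n_traits_with_sets:
                bad_trait = str(rng.choice(traits))
                n_violating += 1
                n_sets += 1
                if rng.uniform() < 0.5:
                    cs_id = f"{bad_trait}_lowz_s{si}"
                    for k, v in enumerate([causal, pool[1]]):
                        cs_rows.append(
                            (cs_id, bad_trait, group, si + 1, v,
                             float(rng.uniform(0, 0.3)),
                             float(rng.uniform(-2.9, 2.9)))
                        )
                else:
                    cs_id = f"{bad_trait}_big_s{si}"
                    for k in range(201):
                        v = causal if k == 0 else make_variant_id(
                            chrom, sig_pos + 500 + k, "C", "T"
                        )
                        cs_rows.append(
                            (cs_id, bad_trait, group, si + 1, v,
                             float(rng.uniform(0, 0.01)), float(rng.uniform(4, 6)))
                        )
        # summary statistics: one row per trait per cis variant
        for trait in traits:
            for k in range(5):
                stat_rows.append(
                    (chrom, base_pos + k, make_variant_id(chrom, base_pos + k, "A", "G"),
                     trait, group,
                     float(rng.normal(0, 0.2)), float(rng.uniform(0.05, 0.2)),
                     float(rng.uniform(0, 1)))
                )

    cs_df = pd.DataFrame(
        cs_rows,
        columns=["cs_id", "trait_id", "group_id", "signal_index",
                 "variant_id", "pip", "z"],
    )
    stats_df = pd.DataFrame(
        stat_rows,
        columns=["chrom", "pos", "variant_id", "trait_id", "group_id",
                 "beta", "se", "p"],
    )
    if out_tsv is not None:
        cs_df.to_csv(out_tsv, sep="\t", index=False)
    truth = CredibleSetTruth(expected, n_violating, n_sets)
    return cs_df, stats_df, truth


def credible_sets_from_frame(df: pd.DataFrame):
    """Assemble CredibleSet objects from the long-format table."""
    from .credfilter import CredibleSet

    out = []
    for cs_id, sub in df.groupby("cs_id", sort=True):
        out.append(
            CredibleSet(
                cs_id=cs_id,
                trait_id=sub["trait_id"].iloc[0],
                group_id=sub["group_id"].iloc[0],
                signal_index=int(sub["signal_index"].iloc[0]),
                variant_ids=frozenset(sub["variant_id"]),
                pips=dict(zip(sub["variant_id"], sub["pip"])),
                zscores=dict(zip(sub["variant_id"], sub["z"])),
            )
        )
    return out


def sim_lbf_pair(
    cfg: SimConfig,
    scenario: str,
    n_variants: int = 100,
    peak: float = 20.0,
) -> tuple[SignalLBF, SignalLBF]:
    """A pair of LBF vectors realising one colocalisation hypothesis.

    H4: both peaked at the same variant; H3: disjoint peaks; H1/H2: one
    peaked, the other flat; H0: both flat. Background LBFs are small
    Gaussian jitter so vectors are not degenerate.
    """
    if scenario not in ("H0", "H1", "H2", "H3", "H4"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    rng = cfg.rng(salt=5)
    variants = tuple(
        make_variant_id(cfg.chrom, 14_000_000 + i, "A", "G")
        for i in range(n_variants)
    )
    l1 = rng.normal(0, 0.05, n_variants)
    l2 = rng.normal(0, 0.05, n_variants)
    if scenario in ("H1", "H3", "H4"):
        l1[0] = peak
    if scenario == "H2":
        l2[0] = peak
    if scenario == "H4":
        l2[0] = peak
    if scenario == "H3":
        l2[1] = peak
    return (
        SignalLBF("sigA", variants, l1),
        SignalLBF("sigB", variants, l2),
    )


def truth_to_json(truth, path: str | Path) -> None:
    """Serialise a truth record (dataclass) to JSON."""
    def default(o):
        if isinstance(o, GenomicInterval):
            return {"chrom": o.chrom, "start": o.start, "end": o.end}
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(asdict(truth), default=default, indent=1))
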