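# Methods

## Coordinate transform

Gene regions are rendered through a piecewise-linear map built on the union
of the displayed transcripts' exons (all panels share one axis). Exon
segments map with scale 1, so exonic distances and interval lengths are
preserved exactly; each gap between consecutive union exons maps linearly
onto a fixed display width, 50 nt by default. The identity

    total display length = Σ exon lengths + 50 × (number of introns)

holds exactly for any structure, and the map is monotone, strictly so
inside exons, where the inverse recovers the genomic position exactly.
Intronic positions interpolate linearly and round-trip only up to the
compression ratio. Book-ended exons (zero-length gap) are treated as
contiguous sequence, not as an intron. Internal coordinates are 0-based
half-open; GFF3 (1-based inclusive) and VCF positions are converted at the
I/O boundary. Maps are built in genomic orientation regardless of strand;
a renderer may flip the display axis for minus-strand genes, but keeping
genomic orientation keeps coverage and annotation panels consistent.

## Coverage stratification

Tracks are read at base resolution (absent intervals are 0), binned to
5 bp by default — each bin is the mean depth of its bases, the trailing
partial bin averaged over its true width — and normalised to depth per
million library reads. When no library size is available the track sum is
used as a fallback, which preserves between-sample comparability of shape
but not of absolute depth. Dosages round to the nearest hard genotype
class, half up; an optional maximum dosage-to-class distance (default 0.5,
i.e. no filtering) can exclude ambiguous imputed dosages. Class means are
unweighted arithmetic means per bin; classes with no samples are omitted.
An optional joint rescale by the global class-mean maximum gives a 0–1
display axis (off by default, on in the figure renderer). The choice to
normalise per sample and average per class, and to scale the whole panel
jointly rather than per class, is a design decision: per-class scaling
would hide the depth differences the plot exists to show.

## Trait normalisation and exon effects

Usage ratios divide each transcript/event by the per-sample total of its
group (gene or splice cluster); a zero group total makes usage undefined
and yields missing values rather than zeros. The inverse normal transform
maps average ranks r to Φ⁻¹((r − 0.5)/n), excluding missing values from n;
the (r − 0.5)/n offset avoids infinite quantiles and is symmetric, and a
constant vector maps to all zeros. Effects are OLS fits of the transformed
exon value on dosage, an intercept, and covariates (by convention the
first six genotype and six trait principal components when provided, via
standard SVD); β and SE come from the dosage coefficient, the 95% CI from
Student's t with n − k − 2 degrees of freedom. Significance is
Benjamini–Hochberg across the exons of the displayed gene only, at
FDR ≤ 1%; genome-wide correction belongs to the upstream mapping pipeline,
not the plot. When batch-mapping, traits with fewer than five variants in
the ±1 Mb cis window around the gene start are excluded. The regression
engine for exon effects is plain OLS with covariates; permutation-based
empirical p-values are out of scope.

## Credible-set filtering

QC drops a credible set when its maximum absolute z-score is below 3 or
its size exceeds 200 variants; both comparisons are strict, so max|z| = 3
and size = 200 survive. The z rule uses the maximum over the set, not the
lead variant. Components are computed within one quantification method and
one group; two sets link when they share at least one variant ID (exact
chr_pos_ref_alt string match), and components are the transitive closure
(networkx; validated against a brute-force closure oracle in the tests).
Per component the representative trait is the one owning the largest
single-variant PIP over member sets; a `sum` rule (summed PIP per trait)
is available behind a flag. Exact PIP ties break to the lexicographically
smallest trait ID, for reproducibility. Filtering keeps only the selected
traits' summary-statistic rows and is idempotent; the pipeline asserts on
every run that the components partition the QC-passing input and that each
selected trait belongs to its component.

## Colocalisation

The engine consumes per-variant natural-log Bayes factors for each
fine-mapped signal and works entirely in log space (log-sum-exp), so peak
LBFs of several hundred are safe. Hypothesis scores are as in the README;
the H3 term is a log-difference, guarded: when the cross term
lse(ℓ₁ + ℓ₂) reaches lse(ℓ₁) + lse(ℓ₂) within 1e-12 — the degenerate
single-shared-variant case — S3 is −∞ and PP3 is exactly 0. Default priors
are p₁ = p₂ = 1e-4 and p₁₂ = 5e-6, the convention of Bayes-factor
colocalisation; they are exposed as options since published analyses do
not always state them. Variants align by exact ID; no allele flipping is
attempted (LBFs are invariant to allele order), so mismatched IDs simply
drop out of the intersection. Pairs with fewer than 10 shared variants are
flagged, with none an error. All-pairs tables cap each side at 10 signals
per locus and flag PP4 strictly greater than 0.9.

## Synthetic data generator

The generator produces every input format the toolkit reads, seeded and
byte-reproducible. Genotypes are Hardy–Weinberg draws at a configurable
allele frequency (default MAF 0.3, 200 samples). Coverage uses a 5-exon
gene (~5.5 kb with introns); every exon has expected depth 50 except the
affected exon, whose inclusion proportion is sigmoid(β(dosage − 1)) — the
splicing archetype; β = 0.8 by default — while an alternative mechanism
multiplies all exons by exp(0.2 β dosage), the expression archetype.
Counts are Poisson by default; a negative-binomial option (dispersion 0.1,
variance μ + 0.1μ²) reflects the overdispersion of real RNA-seq coverage.
Credible-set fixtures plant, per group, 1–3 signals whose member sets all
contain the causal variant (so each signal is one connected component),
give the designated best trait PIP 0.95 against all others below 0.8, and
mix in a known fraction of QC-violating sets (low z or oversized) that
must be dropped without changing any selection; with 1,000 groups of 20
traits this yields a ~90% summary-statistic reduction. LBF fixtures place
a peak of 20 at shared, disjoint, one-sided, or no variants to realise
each colocalisation hypothesis.

What the generator does not emulate: linkage disequilibrium (variants are
exchangeable labels), read-level artefacts (mapping bias, GC content,
duplicates), junction-spanning reads, multi-gene interference, or
relatedness among samples. Passing tests therefore demonstrate the
correctness of the transforms, the filter logic, and the estimators under
their stated models — not robustness to the correlated noise of real data.

## Numerical choices and problem sizes

Exon-effect fits share one design matrix across exons, so a gene's exons
are estimated with a single solve; a zero-variance dosage is an error
("monomorphic variant"). SVG output is byte-deterministic (fixed hash salt
and no embedded date), which makes figure regression tests exact. The test
and acceptance workloads use the documented study conditions — 200
samples, MAF 0.3, depth 50, 50 seeded replicates, 1,000 null exons, 1,000
groups × 20 traits — sizes at which every stochastic check is stable
across seeds while the full suite runs in seconds.

## Known limitations

The toolkit consumes fine-mapping output; it does not run SuSiE or
recompute PIPs, and it does not harmonise variant IDs across datasets.
BAM-to-coverage conversion, GC normalisation, and permutation passes are
deliberately external. The chrX convention ships GRCh38 PAR coordinates as
constants (overridable); male non-PAR dosages are doubled and clipped at
2 with a warning, and samples of unknown sex are left unchanged.
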