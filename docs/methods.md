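# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind the package, and what the test suite does and does
not establish.

## The rainstorm statistic

Input is a cohort of per-patient, per-chromosome sorted mutation position
lists `P_1 … P_g` (within-patient duplicate positions collapsed; positions
shared by several patients kept — the pooled set `P'` is a multiset).
Indels contribute their start position; the method operates purely on
point positions.

For each mutation `p` of patient `q`:

1. **Nearest-genome distances.** For every other genome `j`, the distance
   from `p` to the nearest element of `P_j` (either side) is found by
   binary search. Distances are floored at 1 bp so that coincident
   cross-patient positions remain finite in log space. The `g−1` distances
   are partially sorted and the `k` smallest averaged (`k = 4` by
   default). Averaging over the nearest *distinct* genomes rather than the
   same genome suppresses kataegis-style clusters private to one tumour;
   raising `k` raises the number of genomes a locus must recur in before
   it registers.
2. **Background correction.** The pooled positions are binned
   (non-overlapping bins of `b = 100 kb`, the last bin truncated at the
   chromosome end; a bin's rate is its count over its width, so rates
   integrate to `|P'|`). A loess-style smoother (tricube-weighted local
   quadratic, span 0.3, evaluated at bin midpoints and linearly
   interpolated; hand-written because the available lowess implementations
   are locally linear) yields `L(x)`, clamped below at
   `max(1e−12, 0.01 × mean rate)` to keep logs finite in deserts. The
   correction term is `log(L(p)/μ̄)` — the *relative* local rate. Using
   the rate relative to the chromosome mean rather than the absolute rate
   changes R only by a per-chromosome constant (percentile-based peak
   calling downstream is unaffected) and makes R invariant under a uniform
   rescaling of every patient's load, which is the normalisation property
   the test suite checks.
3. **Load correction.** `log(|P_q|/G)` with `|P_q|` the patient's
   genome-wide mutation total and `G = 2.8e9` bp. Together with term 1
   this cancels cohort-wide density: doubling every load halves the
   distances and doubles `|P_q|`.

Natural log throughout; only relative values matter downstream. Points
are merged across patients and sorted by position (stable patient-order
tie-break, which makes outputs byte-reproducible).

## The doppler peak caller

The signal is `D = −R` ordered by relative position (pooled-multiset
rank), so mutation-dense loci are maxima and the series is uniformly
sampled regardless of genomic spacing.

- **CWT.** Mexican-hat wavelet at dyadic scales {1, 2, 4, 8, 16, 32, 64}
  (PyWavelets). Local maxima per scale row are linked into ridges from the
  coarsest scale down, matching within one scale-width and tolerating up
  to 3 missed scales. Each ridge yields one candidate at its
  maximum-coefficient index.
- **Noise and SNR.** Noise is the 95th percentile of absolute
  smallest-scale coefficients within 500 indices of the apex, *excluding*
  the candidate's own support (apex ± 2 × scale). Without the exclusion a
  wide peak occupies ~5% of its own window and inflates its noise
  estimate, compressing exactly the contrast the caller relies on.
- **Candidate filters.** Ridges must span ≥ 3 scales and peak at scale
  ≥ 8; candidates below an absolute SNR of 10 or below the chromosome's
  95th SNR percentile are removed, and apexes below the 95th percentile of
  D (φ) are removed. The percentile cut-offs are fixed by the published
  procedure; the ridge-length, minimum-scale and absolute-SNR defaults
  were calibrated on this package's synthetic cohorts (below) to make the
  caller's operating characteristics explicit: at 20 patients × 10 Mb ×
  2×10⁻⁵/bp, roughly seven 4-patient coincidences per chromosome satisfy
  the retention arithmetic (4+ distinct patients within ≤ 666 bp gives
  ≥ 6 mutations/kb) by chance, and only the wavelet-support requirements
  separate them from genuine multi-kilobase hotspots. All are
  config-exposed.
- **Boundary refinement.** Initial bounds are apex ± scale. Bounds extend
  outward index-by-index, up to 12 per side, stopping at the first
  mutation with `D` below the 25th percentile (τ). Metrics are then
  counted in genomic space: `n_mutations` (pooled entries in the
  interval), `g_peak` (distinct patients), `m_rate = 1000·n/length`.
  While the retention criteria (`g_peak ≥ 4`, `m_rate ≥ 6`) fail, the
  boundary index with the smaller `D` is dropped — but never past the
  apex, so a candidate cannot drift onto a neighbouring locus — until the
  criteria are met (the largest such interval is kept) or shrinking
  becomes futile (`g_peak` below threshold is unrecoverable). Peaks are
  per-chromosome; adjacent discrete peaks are not merged.
- **Degenerate inputs.** Signals shorter than twice the smallest scale,
  or cohorts with fewer patients than `min_patients`, return no peaks
  with a warning. A single-index peak spans one position (length 1).

Annotation labels each peak CDS / 5'UTR / 3'UTR / Intron (priority in that
order) when it overlaps a gene, 5'Flank / 3'Flank within 2 kb of a gene
span (strand-aware), otherwise Intergenic; ties go to the nearest gene,
then to the first in sorted order.

## Mutation signatures

SNVs are collapsed to the pyrimidine reference strand and counted into the
standard 96 trinucleotide classes per sample. For each candidate signature
number `n`, every bootstrap replicate resamples each sample's column
multinomially at its observed total and factorises it by NMF
(multiplicative updates, Frobenius loss, deterministic NNDSVD-A
initialisation — replicate-to-replicate variation therefore comes from the
resampling alone). Pooled replicate signatures are clustered (k-means on
L2-normalised vectors, which approximates cosine distance on the unit
sphere); stability `S_n` is the mean cosine silhouette clipped to [0, 1].
The consensus takes each cluster's medoid and then polishes it with a
short NMF refinement on the original catalog (initialised at the medoids):
a raw medoid carries one replicate's sampling noise, which both caps
recovery accuracy and can make the reconstruction error non-monotone in
`n`. Exposures are refit by per-sample NNLS with the consensus fixed;
`R_n = ‖V − WH‖_F`. The selected `n` minimises normalised error minus
normalised stability (ties to the smaller `n`; a constant vector
contributes zero). Reference matching is greedy one-to-one on cosine
similarity; leftover discovered signatures are "unassigned". Differential
exposure uses per-sample proportions by default, a two-sided Wilcoxon
rank-sum per signature (exact method for small tie-free samples) and BH
q-values across signatures.

The default bootstrap count is 1000; the test suite and acceptance script
run 50 replicates per candidate `n`, which this package's calibration
experiments show is ample to rank stability at 40-sample catalogs.

## Cohort statistics

- **Fisher's exact test** (scipy) on 2×2 tables; the reported odds ratio
  is the sample estimate `ad/bc` (∞ when `bc = 0` with `ad > 0`); a zero
  margin gives p = 1 with an undefined odds ratio.
- **AID-motif enrichment**: a mutation is a motif hit if its position is
  the focal C of WRCY on either strand (equivalently the G of RGYW on the
  forward strand; motif and focal offset are configurable IUPAC inputs).
  The 2×2 table crosses motif-hit with in-peak over pooled mutation
  *events* (a site shared by three patients counts three times); one-sided
  (enrichment) and two-sided p-values are reported.
- **Subgroup association**: per peak, patients are mutated/unmutated
  (≥ 1 mutation inside the interval) × group A/B; two-sided Fisher with
  BH across peaks and a direction call.
- **Allelic imbalance**: sites need ≥ 12× coverage in DNA *and* RNA (the
  conservative reading of the coverage rule); each tested site gets a
  two-sided Fisher p on `[[dna_ref, dna_alt], [rna_ref, rna_alt]]`, BH
  q-values, significance at Q < 0.1, and a direction from comparing alt
  fractions. Per-gene patient ratios divide patients with ≥ 1 significant
  somatic AI site by patients with ≥ 1 tested somatic site. Intronic-SNP
  exclusion is left to input preparation (`region_label` filtering).

## Synthetic study conditions

`simulate_cohort` draws each patient's positions from an inhomogeneous
Poisson process: background rate `r₀ = 2×10⁻⁵`/bp/patient (the genome-wide
density of a heavily mutated lymphoma genome), multiplied by an optional
log-normal per-patient load factor and a sinusoidal rate field (default
amplitude ±50%, wavelength 5 Mb) standing in for replication-timing
variation; the field is discretised at 1 kb for sampling. Hotspots add
Poisson extras at `background × (multiplier − 1)` inside the interval for
a fixed random subset of patients (default study condition: one 2 kb
hotspot at 50×, recurrent in half of a 20-patient cohort on a 10 Mb
chromosome). With `motif_mode`, a uniform ACGT reference is generated and
hotspot mutations snap to AID-motif focal bases. Signature catalogs are
multinomial draws from planted mixtures; allele counts are binomial per
assay. All generators are pure functions of (config, seed); a guardrail
refuses configurations with more than 10⁷ expected mutations.

What the simulations do **not** emulate: real replication-timing tracks
and chromatin covariates, indel length spectra, purity/subclonality,
sequencing artefacts, and realistic trinucleotide composition of the
genome. Passing tests therefore demonstrate the algorithmic properties
(exactness, normalisation, detection margins at the stated effect sizes,
calibration of the exact tests), not performance on any particular tumour
cohort; real-genome hotspot widths and background inhomogeneity can be
harsher than the sinusoidal surrogate.

## Problem sizes and numerics

Test and acceptance runs use 20-patient, 10 Mb chromosomes (~4,000 pooled
mutations), 20 replicates for recall and 20 matched nulls; signature runs
use 40 samples × 500–2,000 mutations with 50 bootstrap replicates over
n ∈ {2…6}; calibration runs 2,000 null and 1,000 imbalanced allele-count
records. These sizes give Monte-Carlo margins comfortably inside the
asserted bounds while keeping the whole suite in tens of seconds.
Floating-point points files store R at 17 significant digits so round
trips are exact; peak and points writers emit deterministic provenance
headers (no timestamps), making identical inputs byte-identical outputs.

## Known limitations

- The nearest-`k` average needs at least `k+1` genomes with mutations on
  the chromosome; sex chromosomes of small cohorts may fail that bar.
- The loess span (0.3) is tuned for megabase-scale variation at 100 kb
  bins; very short chromosomes fall back to a constant background.
- The wavelet-stage defaults were calibrated at cohort densities around
  0.4–1 pooled mutations/kb; cohorts that are orders of magnitude denser
  or sparser deserve a fresh look at `min_scale_at_max` and `snr_min`.
- Peak annotation uses a minimal gene model (gene span, CDS, UTRs, exons)
  and does not resolve overlapping transcripts.
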