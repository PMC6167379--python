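"""Doppler: wavelet-based delineation of recurrently mutated peaks.

The rainstorm statistic R is negated into a density signal D = -R, indexed
by "relative position" -- the rank of each mutation in the chromosome-wide
sorted pooled multiset -- so that the continuous wavelet transform sees a
uniformly sampled series regardless of how mutations spread along the
chromosome. Candidate peaks are wavelet ridges; they are pruned by
signal-to-noise ratio and apex amplitude (both as within-chromosome
percentiles), boundary-refined on the raw signal, and retained only if at
least ``min_patients`` distinct genomes are mutated inside the interval and
the mutation density reaches ``min_rate`` mutations per kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy.signal import find_peaks

from .cohort import IntervalSet
from .distance import RainstormPoints

__all__ = [
    "DopplerConfig",
    "DensitySignal",
    "WaveletPeak",
    "DopplerPeak",
    "make_density_signal",
    "detect_wavelet_peaks",
    "amplitude_filter",
    "refine_boundaries",
    "call_peaks",
    "annotate_peaks",
]


@dataclass(frozen=True)
class DopplerConfig:
    """Tunables of the peak caller.

    The retention thresholds (``min_patients`` >= 4 genomes, ``min_rate``
    >= 6 mutations/kb), the percentile cut-offs (SNR and apex amplitude at
    the 95th, boundary-extension stop at the 25th) and the 12-index
    boundary-extension limit follow the published procedure. The wavelet
    internals (Mexican-hat mother wavelet, dyadic scales, ridge-linking gap,
    the minimum ridge length and minimum apex scale, and the noise window)
    mirror the defaults of the mass-spectrometry CWT peak detector the
    procedure builds on; all are exposed here.
    """

    scales: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64)
    snr_percentile: float = 95.0
    phi_percentile: float = 95.0
    tau_percentile: float = 25.0
    max_extend: int = 12
    min_patients: int = 4
    min_rate: float = 6.0
    ridge_gap: int = 3
    noise_window: int = 500
    min_ridge_length: int = 3
    min_scale_at_max: int = 8
    snr_min: float = 10.0
    keep_unretained: bool = False


@dataclass
class DensitySignal:
    """Mutation-density series in relative-index space (D = -R)."""

    chromosome: str
    D: np.ndarray
    positions: np.ndarray
    patient_index: np.ndarray
    patients: list[str]

    def __len__(self) -> int:
        return len(self.D)


@dataclass
class WaveletPeak:
    """One CWT ridge candidate, in relative-index coordinates."""

    apex_index: int
    scale_at_max: int
    snr: float
    start_index: int
    end_index: int
    max_coef: float = 0.0
    ridge_length: int = 1


@dataclass
class DopplerPeak:
    """A refined genomic peak interval with its retention metrics."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_mutations: int
    g_peak: int
    m_rate: float
    mean_D: float
    retained: bool
    gene: str | None = None
    region: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def make_density_signal(points: RainstormPoints) -> DensitySignal:
    """Negate R into a density score ordered by relative position."""
    if len(points) == 0:
        raise ValueError("empty rainstorm points")
    order = np.lexsort((points.patient_index, points.positions))
    return DensitySignal(
        chromosome=points.chromosome,
        D=-points.R[order],
        positions=points.positions[order],
        patient_index=points.patient_index[order],
        patients=list(points.patients),
    )


def _link_ridges(
    maxima_per_scale: list[np.ndarray],
    coefs: np.ndarray,
    scales: tuple[int, ...],
    ridge_gap: int,
) -> list[dict]:
    """Link local maxima across scales into ridge lines.

    Starting at the coarsest scale, each ridge is followed downward; at each
    finer scale the nearest local maximum within a window proportional to
    the current scale is appended. A ridge survives up to ``ridge_gap``
    consecutive scales without a match. Maxima not claimed by an existing
    ridge start new ridges at their own scale.
    """
    n_scales = len(scales)
    claimed = [np.zeros(len(m), dtype=bool) for m in maxima_per_scale]
    ridges: list[dict] = []
    for s0 in range(n_scales - 1, -1, -1):
        for j0, idx0 in enumerate(maxima_per_scale[s0]):
            if claimed[s0][j0]:
                continue
            ridge = {"scales": [s0], "indices": [int(idx0)]}
            claimed[s0][j0] = True
            gap = 0
            current = int(idx0)
            for s in range(s0 - 1, -1, -1):
                cand = maxima_per_scale[s]
                window = max(scales[s], 2)
                if len(cand):
                    dist = np.abs(cand - current)
                    jbest = int(np.argmin(dist))
                    if dist[jbest] <= window and not claimed[s][jbest]:
                        claimed[s][jbest] = True
                        current = int(cand[jbest])
                        ridge["scales"].append(s)
                        ridge["indices"].append(current)
                        gap = 0
                        continue
                gap += 1
                if gap > ridge_gap:
                    break
            ridges.append(ridge)
    return ridges


def detect_wavelet_peaks(
    signal: DensitySignal,
    scales: tuple[int, ...] = DopplerConfig.scales,
    snr_percentile: float = DopplerConfig.snr_percentile,
    ridge_gap: int = DopplerConfig.ridge_gap,
    noise_window: int = DopplerConfig.noise_window,
    min_ridge_length: int = DopplerConfig.min_ridge_length,
    min_scale_at_max: int = DopplerConfig.min_scale_at_max,
    snr_min: float = 0.0,
) -> list[WaveletPeak]:
    """Mexican-hat CWT peak candidates in relative-index space.

    Each ridge yields one candidate with apex at its maximum-coefficient
    index; SNR is the apex coefficient over the local noise level: the 95th
    percentile of absolute smallest-scale coefficients within
    ``noise_window`` indices of the apex, excluding the candidate's own
    support (apex +/- 2 x scale) so that wide peaks do not inflate their
    own noise estimate. Ridges shorter than ``min_ridge_length`` scales or
    peaking below ``min_scale_at_max`` are dropped as noise spikes;
    surviving candidates below ``snr_min`` or below the
    ``snr_percentile``-th percentile of non-negative SNRs are removed. Pass
    ``snr_percentile=0`` (and ``snr_min=0``) to disable SNR pruning.
    """
    d = np.asarray(signal.D, dtype=float)
    n = len(d)
    scales = tuple(sorted(scales))
    if n < 2 * scales[0]:
        warnings.warn("signal too short for wavelet analysis; no peaks")
        return []
    usable = tuple(s for s in scales if 2 * s <= n)
    coefs, _ = pywt.cwt(d - d.mean(), usable, "mexh")

    maxima = []
    for row in coefs:
        locs, _ = find_peaks(row)
        maxima.append(locs)
    ridges = _link_ridges(maxima, coefs, usable, ridge_gap)

    half = max(noise_window // 2, 1)
    small = np.abs(coefs[0])
    peaks: list[WaveletPeak] = []
    for ridge in ridges:
        coef_vals = [coefs[s, i] for s, i in zip(ridge["scales"], ridge["indices"])]
        jmax = int(np.argmax(coef_vals))
        apex = ridge["indices"][jmax]
        scale = usable[ridge["scales"][jmax]]
        max_coef = float(coef_vals[jmax])
        if max_coef <= 0:
            continue
        if len(ridge["scales"]) < min_ridge_length or scale < min_scale_at_max:
            continue
        lo, hi = max(0, apex - half), min(n, apex + half)
        keep = np.ones(hi - lo, dtype=bool)
        exc_lo = max(lo, apex - 2 * scale)
        exc_hi = min(hi, apex + 2 * scale + 1)
        keep[exc_lo - lo : exc_hi - lo] = False
        window_vals = small[lo:hi][keep]
        if not len(window_vals):
            window_vals = small[lo:hi]
        noise = float(np.percentile(window_vals, 95))
        snr = max_coef / max(noise, 1e-12)
        peaks.append(
            WaveletPeak(
                apex_index=int(apex),
                scale_at_max=int(scale),
                snr=snr,
                start_index=max(0, apex - scale),
                end_index=min(n - 1, apex + scale),
                max_coef=max_coef,
                ridge_length=len(ridge["scales"]),
            )
        )
    if not peaks:
        return []
    snrs = np.array([p.snr for p in peaks])
    valid = snrs[snrs >= 0]
    thr = float(snr_min)
    if snr_percentile > 0 and len(valid):
        thr = max(thr, float(np.percentile(valid, snr_percentile)))
    peaks = [p for p in peaks if p.snr >= thr]
    peaks.sort(key=lambda p: p.apex_index)
    return peaks


def amplitude_filter(
    peaks: list[WaveletPeak],
    signal: DensitySignal,
    phi_percentile: float = DopplerConfig.phi_percentile,
) -> list[WaveletPeak]:
    """Keep candidates whose apex density reaches the chromosome-wide
    ``phi_percentile``-th percentile of D (apex exactly at phi is kept)."""
    if not 0 < phi_percentile < 100:
        raise ValueError("phi_percentile must lie in (0, 100)")
    phi = np.percentile(signal.D, phi_percentile)
    return [p for p in peaks if signal.D[p.apex_index] >= phi]


def refine_boundaries(
    peak: WaveletPeak,
    signal: DensitySignal,
    tau: float,
    max_extend: int = DopplerConfig.max_extend,
    min_patients: int = DopplerConfig.min_patients,
    min_rate: float = DopplerConfig.min_rate,
) -> DopplerPeak:
    """Refine one candidate into a genomic peak and test retention.

    Boundaries first extend outward index-by-index, up to ``max_extend``
    indices per side, stopping at the first mutation with D below ``tau``
    (the 25th-percentile level of the chromosome). The interval is then
    converted to genomic coordinates; while the retention criteria fail and
    the interval can still shrink, the boundary index with the smaller D is
    removed. The peak keeps the largest interval along that path that meets
    both criteria, or is flagged not retained.
    """
    d = signal.D
    n = len(d)
    s = int(np.clip(peak.start_index, 0, n - 1))
    e = int(np.clip(peak.end_index, 0, n - 1))

    for _ in range(max_extend):
        if s - 1 < 0 or d[s - 1] < tau:
            break
        s -= 1
    for _ in range(max_extend):
        if e + 1 >= n or d[e + 1] < tau:
            break
        e += 1

    def metrics(si: int, ei: int) -> tuple[int, int, int, int, float]:
        start = int(signal.positions[si])
        end = int(signal.positions[ei])
        n_mut = ei - si + 1  # every index is one pooled mutation
        g = len(np.unique(signal.patient_index[si : ei + 1]))
        length = end - start + 1
        return start, end, n_mut, g, 1000.0 * n_mut / length

    apex = int(np.clip(peak.apex_index, s, e))
    start, end, n_mut, g, m_rate = metrics(s, e)
    retained = g >= min_patients and m_rate >= min_rate
    while not retained and s < e:
        if g < min_patients:
            break  # shrinking can only lose patients; impossible to meet
        # The peak stays anchored at its wavelet apex: boundaries may not
        # cross it, so a candidate cannot drift onto a different locus.
        if s == apex:
            e -= 1
        elif e == apex:
            s += 1
        elif d[s] <= d[e]:
            s += 1
        else:
            e -= 1
        start, end, n_mut, g, m_rate = metrics(s, e)
        retained = g >= min_patients and m_rate >= min_rate

    return DopplerPeak(
        chromosome=signal.chromosome,
        start=start,
        end=end,
        n_mutations=n_mut,
        g_peak=g,
        m_rate=m_rate,
        mean_D=float(np.mean(d[s : e + 1])),
        retained=retained,
    )


def call_peaks(points: RainstormPoints, config: DopplerConfig | None = None) -> list[DopplerPeak]:
    """Full per-chromosome pipeline: density signal -> CWT candidates ->
    SNR and amplitude pruning -> boundary refinement -> retained peaks.

    Overlapping retained peaks are deliberately not merged; adjacent
    discrete peaks are reported as-is. Non-retained peaks are included,
    flagged, only when ``config.keep_unretained`` is set.
    """
    cfg = config or DopplerConfig()
    n_patients = len(np.unique(points.patient_index))
    if n_patients < cfg.min_patients:
        warnings.warn(
            f"cohort has {n_patients} patients on {points.chromosome}; "
            f"fewer than min_patients={cfg.min_patients}: no retained peak possible"
        )
        return []
    signal = make_density_signal(points)
    candidates = detect_wavelet_peaks(
        signal,
        scales=cfg.scales,
        snr_percentile=cfg.snr_percentile,
        ridge_gap=cfg.ridge_gap,
        noise_window=cfg.noise_window,
        min_ridge_length=cfg.min_ridge_length,
        min_scale_at_max=cfg.min_scale_at_max,
        snr_min=cfg.snr_min,
    )
    candidates = amplitude_filter(candidates, signal, cfg.phi_percentile)
    tau = float(np.percentile(signal.D, cfg.tau_percentile))
    refined = [
        refine_boundaries(
            c, signal, tau,
            max_extend=cfg.max_extend,
            min_patients=cfg.min_patients,
            min_rate=cfg.min_rate,
        )
        for c in candidates
    ]
    out = [p for p in refined if p.retained or cfg.keep_unretained]
    out.sort(key=lambda p: (p.chromosome, p.start, p.end))
    # Drop exact duplicates (two ridges can refine to the same interval).
    dedup: list[DopplerPeak] = []
    for p in out:
        if dedup and (dedup[-1].chromosome, dedup[-1].start, dedup[-1].end) == (
            p.chromosome, p.start, p.end
        ):
            continue
        dedup.append(p)
    return dedup


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Gene spans with optional sub-features for peak annotation."""

    genes: list[dict] = field(default_factory=list)
    # each: {name, chromosome, start, end, strand, cds: [(s,e)],
    #        utr5: [(s,e)], utr3: [(s,e)], exons: [(s,e)]}

    @classmethod
    def from_gff3(cls, path: str) -> "GeneModel":
        import gffutils

        from .cohort import normalize_chrom

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            name = (
                feat.attributes.get("gene_name", [None])[0]
                or feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("ID", ["gene"])[0]
            )
            entry = {
                "name": name,
                "chromosome": normalize_chrom(feat.seqid),
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "cds": [],
                "utr5": [],
                "utr3": [],
                "exons": [],
            }
            for child in db.children(feat.id):
                span = (child.start, child.end)
                ftype = child.featuretype.lower()
                if ftype == "cds":
                    entry["cds"].append(span)
                elif ftype in ("five_prime_utr", "5'utr"):
                    entry["utr5"].append(span)
                elif ftype in ("three_prime_utr", "3'utr"):
                    entry["utr3"].append(span)
                elif ftype == "exon":
                    entry["exons"].append(span)
            genes.append(entry)
        genes.sort(key=lambda g: (g["chromosome"], g["start"], g["name"]))
        return cls(genes)


def _overlap(a_start: int, a_end: int, spans: list[tuple[int, int]]) -> bool:
    return any(s <= a_end and e >= a_start for s, e in spans)


def annotate_peaks(
    peaks: list[DopplerPeak],
    genes: GeneModel | None,
    flank_bp: int = 2000,
) -> list[DopplerPeak]:
    """Label each peak with its nearest/overlapping gene and a region label.

    Region priority when overlapping a gene: CDS > 5'UTR > 3'UTR > Intron.
    A peak within ``flank_bp`` upstream of a gene (strand-aware) is 5'Flank,
    downstream 3'Flank; otherwise Intergenic. Ties go to the closest gene,
    then to the first gene in sorted order.
    """
    if genes is None or not genes.genes:
        warnings.warn("no gene model given; labelling all peaks Intergenic")
        return [replace(p, gene=None, region="Intergenic") for p in peaks]

    out = []
    for pk in peaks:
        best: tuple[int, int, str, str] | None = None  # (distance, order, gene, region)
        for order, g in enumerate(genes.genes):
            if g["chromosome"] != pk.chromosome:
                continue
            if g["start"] <= pk.end and g["end"] >= pk.start:
                if _overlap(pk.start, pk.end, g["cds"]):
                    region = "CDS"
                elif _overlap(pk.start, pk.end, g["utr5"]):
                    region = "5'UTR"
                elif _overlap(pk.start, pk.end, g["utr3"]):
                    region = "3'UTR"
                else:
                    region = "Intron"
                cand = (0, order, g["name"], region)
            else:
                if pk.start > g["end"]:
                    dist = pk.start - g["end"]
                    side = "3'Flank" if g["strand"] == "+" else "5'Flank"
                else:
                    dist = g["start"] - pk.end
                    side = "5'Flank" if g["strand"] == "+" else "3'Flank"
                if dist > flank_bp:
                    continue
                cand = (dist, order, g["name"], side)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            out.append(replace(pk, gene=None, region="Intergenic"))
        else:
            out.append(replace(pk, gene=best[2], region=best[3]))
    return out
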