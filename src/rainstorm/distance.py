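"""The rainstorm statistic: cohort-wide, background-corrected
inter-mutation distance.

For each mutation of each patient the statistic is

    R = log(mean distance to the nearest mutation in each of the k
            nearest other genomes)
      + log(local background factor)
      + log(|P_q| / G)

where |P_q| is the patient's genome-wide mutation total and G a genome-size
scaling constant (default 2.8e9 bp). The local background factor is a
loess-smoothed estimate of the cohort mutation rate at the mutation's own
position, normalised by the chromosome-wide mean rate, so that R is
invariant under a uniform rescaling of every patient's mutation load while
still cancelling megabase-scale (replication-timing-like) rate variation.
Dense recurrently mutated loci have low R. Natural log throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, IntervalSet

__all__ = [
    "GENOME_SIZE",
    "RateModel",
    "RainstormPoints",
    "bin_mutation_rate",
    "fit_local_rate",
    "nearest_k_mean_distance",
    "compute_rainstorm",
    "render_rainstorm_plot",
]

#: Genome-size scaling constant (bp) used in the per-patient load correction.
GENOME_SIZE = 2.8e9

#: Default bin length for the binned background rate (bp).
DEFAULT_BIN = 100_000

#: Default number of nearest other genomes averaged per mutation.
DEFAULT_K = 4

#: Coincident cross-patient positions would give log(0); distances are
#: floored here (bp).
DISTANCE_FLOOR = 1


@dataclass
class RateModel:
    """Binned local mutation rate with a smooth loess-style evaluator.

    ``bin_rates`` are pooled mutations per bp per cohort in each bin;
    ``smoothed`` holds the local-regression fit at the bin midpoints, and
    evaluation at arbitrary positions interpolates linearly between
    midpoints (constant beyond the outermost midpoints). Values are clamped
    below at ``rate_floor`` to keep log(L) finite in empty regions.
    """

    bin_length: int
    bin_midpoints: np.ndarray
    bin_rates: np.ndarray
    smoothed: np.ndarray
    rate_floor: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        vals = np.interp(np.asarray(x, dtype=float), self.bin_midpoints, self.smoothed)
        return np.maximum(vals, self.rate_floor)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.bin_rates))


@dataclass
class RainstormPoints:
    """Per-mutation adjusted inter-mutation distances for one chromosome.

    Parallel arrays sorted by position; one entry per pooled mutation.
    ``log_mean_dist`` keeps the uncorrected first term (log of the
    mean nearest-genome distance) for diagnostics.
    """

    chromosome: str
    positions: np.ndarray
    patient_index: np.ndarray
    R: np.ndarray
    patients: list[str]
    k: int = DEFAULT_K
    genome_size: float = GENOME_SIZE
    log_mean_dist: np.ndarray | None = None
    patient_totals: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "position": self.positions,
                "patient_id": [self.patients[i] for i in self.patient_index],
                "R": self.R,
            }
        )


def bin_mutation_rate(
    pooled: np.ndarray, chrom_length: int, b: int = DEFAULT_BIN
) -> tuple[np.ndarray, np.ndarray]:
    """Bin the pooled mutation positions into non-overlapping windows of
    length ``b`` tiling [1, chrom_length] and return (midpoints, rates).

    The final bin is truncated at the chromosome end; each bin's rate is its
    mutation count divided by its width in bp, so rates integrate back to
    the pooled count.
    """
    if b < 1 or chrom_length < 1:
        raise ValueError("bin length and chromosome length must be >= 1")
    pooled = np.asarray(pooled)
    n_bins = int(np.ceil(chrom_length / b))
    edges = np.minimum(np.arange(n_bins + 1, dtype=np.int64) * b, chrom_length)
    # np.histogram bins are half-open [lo, hi); positions are integers in
    # [1, l], so edges at multiples of b give bins (lo, lo+1..hi] as needed,
    # except we must include l itself in the last bin.
    counts, _ = np.histogram(pooled, bins=edges + 0.5)
    widths = np.diff(edges).astype(float)
    midpoints = (edges[:-1] + 1 + edges[1:]) / 2.0
    rates = counts / widths
    return midpoints, rates


def _loess_fit(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Local polynomial regression with tricube weights, evaluated at x."""
    n = len(x)
    r = max(degree + 1, int(np.ceil(span * n)))
    r = min(r, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, r - 1)[:r]
        h = max(d[idx].max(), 1e-300)
        w = (1 - np.clip(d[idx] / h, 0, 1) ** 3) ** 3
        pos = w > 0
        deg = min(degree, int(pos.sum()) - 1)
        if deg < 1:
            out[i] = y[i]
            continue
        # x is rescaled by the window half-width for conditioning
        coef = np.polyfit((x[idx][pos] - x[i]) / h, y[idx][pos], deg,
                          w=np.sqrt(w[pos]))
        out[i] = coef[-1]
    return out


def fit_local_rate(
    midpoints: np.ndarray,
    rates: np.ndarray,
    bin_length: int = DEFAULT_BIN,
    span: float = 0.3,
    degree: int = 2,
    floor_policy: str = "relative",
) -> RateModel:
    """Fit a loess-style smoother to the binned rates.

    With fewer than four bins, or all-zero rates, the model falls back to a
    constant. ``floor_policy="relative"`` sets the floor to
    max(1e-12, 0.01 x mean rate); ``"absolute"`` uses 1e-12.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    rates = np.asarray(rates, dtype=float)
    mean_rate = float(np.mean(rates)) if len(rates) else 0.0
    if floor_policy == "relative":
        floor = max(1e-12, 0.01 * mean_rate)
    else:
        floor = 1e-12
    if not np.any(rates > 0):
        warnings.warn("all-zero mutation rates; using constant floor rate")
        smoothed = np.full_like(rates, floor)
    elif len(midpoints) < 4:
        smoothed = np.full_like(rates, max(mean_rate, floor))
    else:
        smoothed = _loess_fit(midpoints, rates, span, degree)
    smoothed = np.maximum(smoothed, floor)
    return RateModel(
        bin_length=bin_length,
        bin_midpoints=midpoints,
        bin_rates=rates,
        smoothed=smoothed,
        rate_floor=floor,
    )


def nearest_k_mean_distance(
    query: np.ndarray,
    others: list[np.ndarray],
    k: int = DEFAULT_K,
    distance_floor: int = DISTANCE_FLOOR,
) -> np.ndarray:
    """Mean distance from each query position to its k nearest other genomes.

    For each query position and each other genome, the distance to that
    genome's nearest mutation (on either side) is found by binary search on
    the sorted position list; distances are floored at ``distance_floor``.
    The per-genome distances of each query position are then partially
    sorted and the k smallest averaged. Genomes with no mutations on the
    chromosome contribute an infinite sentinel; an error is raised only if a
    row ends up with fewer than k finite distances.
    """
    query = np.asarray(query, dtype=np.int64)
    if k > len(others):
        raise ValueError(f"k={k} exceeds the number of other genomes ({len(others)})")
    nq = len(query)
    dists = np.full((len(others), nq), np.inf)
    for j, pos in enumerate(others):
        pos = np.asarray(pos, dtype=np.int64)
        if len(pos) == 0:
            continue
        idx = np.searchsorted(pos, query)
        left = np.where(idx > 0, query - pos[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(idx < len(pos), pos[np.minimum(idx, len(pos) - 1)] - query, np.iinfo(np.int64).max)
        dists[j] = np.minimum(left, right)
    dists = np.maximum(dists, distance_floor)
    if len(others) == k:
        smallest = dists
    else:
        smallest = np.partition(dists, k - 1, axis=0)[:k]
    if not np.all(np.isfinite(smallest)):
        raise ValueError(
            "fewer than k other genomes carry mutations on this chromosome"
        )
    return smallest.mean(axis=0)


def compute_rainstorm(
    cohort: Cohort,
    chromosome: str,
    k: int = DEFAULT_K,
    b: int = DEFAULT_BIN,
    genome_size: float = GENOME_SIZE,
) -> RainstormPoints:
    """Compute the rainstorm statistic for every mutation on a chromosome.

    Entries from all patients are merged and sorted by genomic position
    (stable in patient order on ties), one entry per pooled mutation.
    """
    if chromosome not in cohort.pooled:
        raise ValueError(f"chromosome {chromosome!r} absent from cohort")
    pooled_pos, _pooled_lab = cohort.pooled[chromosome]
    present = [
        p for p in cohort.patients if len(cohort.patient_positions(p, chromosome))
    ]
    if len(present) < k + 1:
        raise ValueError(
            f"need at least k+1={k + 1} patients with mutations on {chromosome}, "
            f"found {len(present)}"
        )
    chrom_length = cohort.chrom_lengths[chromosome]
    midpoints, rates = bin_mutation_rate(pooled_pos, chrom_length, b)
    model = fit_local_rate(midpoints, rates, bin_length=b)
    # Relative background: smoothed local rate over chromosome mean rate.
    mean_rate = max(model.mean_rate, model.rate_floor)

    totals = {p: cohort.patient_total(p) for p in cohort.patients}

    all_pos, all_pat, all_r, all_raw = [], [], [], []
    pidx = {p: i for i, p in enumerate(cohort.patients)}
    for q in present:
        pq = cohort.patient_positions(q, chromosome)
        others = [
            cohort.patient_positions(p, chromosome) for p in cohort.patients if p != q
        ]
        mean_dist = nearest_k_mean_distance(pq, others, k=k)
        log_dist = np.log(mean_dist)
        log_rate = np.log(model(pq) / mean_rate)
        load = np.log(totals[q] / genome_size)
        all_pos.append(pq)
        all_pat.append(np.full(len(pq), pidx[q], dtype=np.int64))
        all_r.append(log_dist + log_rate + load)
        all_raw.append(log_dist)

    positions = np.concatenate(all_pos)
    patients = np.concatenate(all_pat)
    r_vals = np.concatenate(all_r)
    raw = np.concatenate(all_raw)
    order = np.lexsort((patients, positions))  # position first, patient tie-break
    return RainstormPoints(
        chromosome=chromosome,
        positions=positions[order],
        patient_index=patients[order],
        R=r_vals[order],
        patients=list(cohort.patients),
        k=k,
        genome_size=genome_size,
        log_mean_dist=raw[order],
        patient_totals=totals,
    )


def render_rainstorm_plot(
    points: RainstormPoints,
    path: str,
    highlight: IntervalSet | None = None,
) -> None:
    """Scatter the (position, R) cloud, one colour per patient, with alpha
    blending; optional intervals (e.g. called peaks) are shaded."""
    if len(points) == 0:
        raise ValueError("cannot plot empty rainstorm points")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 4))
    cmap = plt.get_cmap("tab20")
    n_pat = max(len(points.patients), 1)
    colors = [cmap(i % 20) for i in points.patient_index]
    ax.scatter(points.positions, points.R, s=4, c=colors, alpha=0.5, linewidths=0)
    if highlight is not None:
        for chrom, start, end, _name in highlight:
            if chrom == points.chromosome:
                ax.axvspan(start, end, color="0.85", zorder=0)
    ax.set_xlabel(f"position on chromosome {points.chromosome} (bp)")
    ax.set_ylabel("rainstorm R")
    ax.set_title(f"{n_pat} genomes, {len(points)} mutations")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
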