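"""Synthetic cohorts with known ground truth.

Generators for (i) per-patient genome-wide mutation loads with smooth
megabase-scale rate variation (a replication-timing surrogate) and injected
multi-patient hotspots, (ii) trinucleotide signature-mixture catalogs, and
(iii) DNA/RNA allele-count pairs with configurable imbalance. Everything is
a pure function of (config, seed), so every pipeline stage can be tested
against a planted truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, build_cohort, MutationRecord, VariantClass
from .signatures import MutationCatalog, CLASSES_96
from .stats import AICountRecord, motif_focal_positions

__all__ = [
    "Hotspot",
    "SimCohortConfig",
    "TruthSet",
    "simulate_cohort",
    "simulate_reference",
    "simulate_signature_catalog",
    "simulate_ai_counts",
]

#: Guardrail: refuse configurations whose expected mutation total is absurd.
MAX_EXPECTED_MUTATIONS = 10_000_000


@dataclass(frozen=True)
class Hotspot:
    """One injected hotspot: a ``width``-bp interval centred at ``center``
    whose mutation intensity is multiplied by ``rate_multiplier`` in a
    random ``recurrence`` fraction of patients (fixed per hotspot)."""

    center: int
    width: int = 2000
    rate_multiplier: float = 50.0
    recurrence: float = 0.5

    def interval(self) -> tuple[int, int]:
        half = self.width // 2
        return self.center - half + 1, self.center - half + self.width

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("hotspot width must be >= 1")
        if not 0 < self.recurrence <= 1:
            raise ValueError("recurrence fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SimCohortConfig:
    """Study conditions for a simulated cohort chromosome.

    Defaults give 20 patients on a 10 Mb chromosome at a background of
    2e-5 mutations per bp per patient (200 expected mutations each, about
    the genome-wide density of a heavily mutated lymphoma genome), with a
    two-fold sinusoidal rate field of 5 Mb wavelength standing in for
    replication-timing variation and a modest log-normal spread of
    per-patient loads.
    """

    n_patients: int = 20
    chrom_length: int = 10_000_000
    chromosome: str = "1"
    background_rate: float = 2e-5
    modulation_amplitude: float = 0.5
    modulation_wavelength: float = 5_000_000.0
    load_sigma: float = 0.0
    hotspots: tuple[Hotspot, ...] = ()
    motif_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background rate must be positive")
        if not 0 <= self.modulation_amplitude < 1:
            raise ValueError("modulation amplitude must lie in [0, 1)")


@dataclass
class TruthSet:
    """Planted ground truth for a simulated cohort."""

    hotspot_intervals: list[tuple[str, int, int]]
    hotspot_patients: list[list[str]]
    patient_loads: dict[str, float]
    reference: dict[str, str] | None = None


def _rate_field(x: np.ndarray, cfg: SimCohortConfig) -> np.ndarray:
    """Smooth multiplicative rate modulation evaluated at positions x."""
    if cfg.modulation_amplitude == 0:
        return np.ones_like(x, dtype=float)
    return 1.0 + cfg.modulation_amplitude * np.sin(
        2 * np.pi * np.asarray(x, dtype=float) / cfg.modulation_wavelength
    )


def _sample_inhomogeneous(
    rng: np.random.Generator, cfg: SimCohortConfig, rate: float
) -> np.ndarray:
    """Positions from an inhomogeneous Poisson process with per-bp rate
    ``rate`` x the smooth field, via a 1 kb discretisation of the field."""
    grid = 1000
    n_cells = int(np.ceil(cfg.chrom_length / grid))
    centers = np.minimum(np.arange(n_cells) * grid + grid // 2, cfg.chrom_length)
    widths = np.diff(np.minimum(np.arange(n_cells + 1) * grid, cfg.chrom_length))
    weights = _rate_field(centers, cfg) * widths
    total = rate * weights.sum()
    n = rng.poisson(total)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    cells = rng.choice(n_cells, size=n, p=weights / weights.sum())
    offsets = rng.integers(0, widths[cells], size=n)
    pos = np.minimum(cells * grid + 1 + offsets, cfg.chrom_length)
    return np.sort(pos).astype(np.int64)


def simulate_cohort(config: SimCohortConfig) -> tuple[Cohort, TruthSet]:
    """Draw a cohort from the configured point process plus hotspots.

    Deterministic under ``config.seed``. Hotspot mutations for each
    hotspot's fixed recurrent patient subset are added at intensity
    background x (rate_multiplier - 1), so the in-hotspot density is the
    multiplier times background. With ``motif_mode`` a random reference
    sequence is generated and hotspot mutations snap to AID-motif focal
    bases within the hotspot.
    """
    cfg = config
    expected = cfg.n_patients * cfg.background_rate * cfg.chrom_length
    if expected > MAX_EXPECTED_MUTATIONS:
        raise ValueError(
            f"expected mutation total {expected:.3g} exceeds the "
            f"{MAX_EXPECTED_MUTATIONS:.0e} guardrail"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2024]))
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    loads = {
        p: float(np.exp(rng.normal(0.0, cfg.load_sigma))) if cfg.load_sigma else 1.0
        for p in patients
    }

    reference = None
    motif_positions: dict[tuple[int, int], np.ndarray] = {}
    if cfg.motif_mode:
        seq = _random_sequence(rng, cfg.chrom_length)
        reference = {cfg.chromosome: seq}
        focal = motif_focal_positions(seq)
        for h in cfg.hotspots:
            lo, hi = h.interval()
            motif_positions[(lo, hi)] = focal[(focal >= lo) & (focal <= hi)]

    hotspot_patients: list[list[str]] = []
    for h in cfg.hotspots:
        n_rec = max(1, int(round(h.recurrence * cfg.n_patients)))
        chosen = sorted(rng.choice(patients, size=n_rec, replace=False).tolist())
        hotspot_patients.append(chosen)

    positions: dict[str, np.ndarray] = {}
    for p in patients:
        pos = _sample_inhomogeneous(rng, cfg, cfg.background_rate * loads[p])
        extra_parts = [pos]
        for h, chosen in zip(cfg.hotspots, hotspot_patients):
            if p not in chosen:
                continue
            lo, hi = h.interval()
            lam = cfg.background_rate * loads[p] * (h.rate_multiplier - 1) * h.width
            n_extra = rng.poisson(lam)
            if n_extra == 0:
                continue
            focal = motif_positions.get((lo, hi))
            if focal is not None and len(focal):
                extra = rng.choice(focal, size=n_extra)
            else:
                extra = rng.integers(lo, hi + 1, size=n_extra)
            extra_parts.append(extra.astype(np.int64))
        positions[p] = np.unique(np.concatenate(extra_parts))

    records = [
        MutationRecord(p, cfg.chromosome, int(x), "N", "A", VariantClass.OTHER)
        for p in patients
        for x in positions[p]
    ]
    cohort = build_cohort(records, {cfg.chromosome: cfg.chrom_length})
    truth = TruthSet(
        hotspot_intervals=[
            (cfg.chromosome, *h.interval()) for h in cfg.hotspots
        ],
        hotspot_patients=hotspot_patients,
        patient_loads=loads,
        reference=reference,
    )
    return cohort, truth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(codes[rng.integers(0, 4, size=length)]).decode("ascii")


def simulate_reference(length: int, seed: int = 0, chromosome: str = "1") -> dict[str, str]:
    """An i.i.d. uniform ACGT reference sequence keyed by chromosome."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    return {chromosome: _random_sequence(rng, length)}


def simulate_signature_catalog(
    signatures: np.ndarray,
    exposures: np.ndarray,
    totals,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> MutationCatalog:
    """Multinomial catalog draws from a planted signature mixture.

    ``signatures`` is 96 x n with columns summing to 1; ``exposures`` is
    n x s with columns summing to 1; ``totals`` gives each sample's
    mutation count, matched exactly in the output column sums.
    """
    W = np.asarray(signatures, dtype=float)
    E = np.asarray(exposures, dtype=float)
    totals = np.asarray(totals, dtype=np.int64)
    if W.shape[0] != 96:
        raise ValueError("signatures must have 96 rows")
    if W.shape[1] != E.shape[0]:
        raise ValueError("signature/exposure dimension mismatch")
    if E.shape[1] != len(totals):
        raise ValueError("exposures/totals dimension mismatch")
    if not (np.allclose(W.sum(axis=0), 1) and np.allclose(E.sum(axis=0), 1)):
        raise ValueError("signature and exposure columns must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 96]))
    probs = W @ E  # 96 x s channel distributions
    matrix = np.column_stack(
        [rng.multinomial(int(t), probs[:, j]) for j, t in enumerate(totals)]
    )
    ids = sample_ids or [f"S{j + 1:03d}" for j in range(len(totals))]
    return MutationCatalog(matrix=matrix, sample_ids=ids, class_labels=list(CLASSES_96))


def simulate_ai_counts(
    n_records: int,
    dna_depth: int = 50,
    rna_depth: int = 50,
    dna_alt_frac: float = 0.5,
    rna_alt_frac: float = 0.5,
    seed: int = 0,
    gene: str = "GENE1",
) -> list[AICountRecord]:
    """Binomial DNA/RNA allele-count pairs, one patient per record."""
    if not (0 <= dna_alt_frac <= 1 and 0 <= rna_alt_frac <= 1):
        raise ValueError("allele fractions must lie in [0, 1]")
    if min(dna_depth, rna_depth) < 1:
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    out = []
    for i in range(n_records):
        dna_alt = int(rng.binomial(dna_depth, dna_alt_frac))
        rna_alt = int(rng.binomial(rna_depth, rna_alt_frac))
        out.append(
            AICountRecord(
                patient_id=f"P{i + 1:04d}",
                gene=gene,
                chromosome="1",
                position=1000 + i,
                dna_ref=dna_depth - dna_alt,
                dna_alt=dna_alt,
                rna_ref=rna_depth - rna_alt,
                rna_alt=rna_alt,
            )
        )
    return out
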