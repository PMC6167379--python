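"""Cohort-level statistics around the called peaks.

Three analyses: enrichment of mutations at AID hotspot motifs inside
versus outside peaks, per-peak association of mutation status with a
binary molecular subgroup, and DNA-versus-RNA allelic-imbalance testing of
per-site allele counts. All use Fisher's exact test on 2x2 tables with
Benjamini-Hochberg FDR control where multiple tests are run.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

__all__ = [
    "Contingency2x2",
    "AICountRecord",
    "AIDirection",
    "fisher_exact_2x2",
    "bh_adjust",
    "motif_focal_positions",
    "aid_motif_enrichment",
    "peak_group_association",
    "allelic_imbalance_test",
    "ai_patient_ratio",
    "read_ai_counts",
]

#: Canonical AID hotspot motif on the pyrimidine strand (W=A/T, R=A/G,
#: Y=C/T); the mutated base is the C at (0-based) offset 2. Its reverse
#: complement RGYW, with the mutated G at offset 1, is scanned implicitly.
AID_MOTIF = "WRCY"
AID_FOCAL_OFFSET = 2

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Contingency2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


class AIDirection(enum.Enum):
    FAVOURS_ALT = "favours_alt"
    FAVOURS_REF = "favours_ref"
    NONE = "none"


@dataclass
class AICountRecord:
    """Per-site DNA and RNA allele counts with test annotations."""

    patient_id: str
    gene: str
    chromosome: str
    position: int
    dna_ref: int
    dna_alt: int
    rna_ref: int
    rna_alt: int
    is_somatic: bool = True
    p: float | None = None
    q: float | None = None
    significant: bool = False
    direction: AIDirection = AIDirection.NONE


def fisher_exact_2x2(
    table: Contingency2x2, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p). The odds ratio is the sample estimate
    a*d / (b*c) (inf when b*c == 0 and a*d > 0, nan for a degenerate
    table); the p-value is the exact hypergeometric tail, two-sided by
    summing tables at fixed margins with probability <= that observed. A
    table with a zero margin gives p = 1 and an undefined (nan) odds ratio.
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if 0 in row or 0 in col:
        return float("nan"), 1.0
    _, p = _scipy_fisher(arr, alternative=alternative)
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        odds = float("inf") if num > 0 else float("nan")
    else:
        odds = num / den
    return odds, float(p)


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p_values = list(p_values)
    if not p_values:
        return []
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(x) for x in q]


def motif_focal_positions(
    sequence: str,
    motif: str = AID_MOTIF,
    focal_offset: int = AID_FOCAL_OFFSET,
) -> np.ndarray:
    """1-based positions of the motif's focal base on either strand.

    The IUPAC ``motif`` is scanned on the forward strand (focal base at
    ``focal_offset``, 0-based) and as its reverse complement (the focal base
    mapping to the mirrored offset), with overlapping matches allowed.
    """
    seq = sequence.upper()
    fwd = "".join(_IUPAC[b] for b in motif.upper())
    rc_motif = motif.upper().translate(_COMP)[::-1]
    rev = "".join(_IUPAC[b] for b in rc_motif)
    rc_offset = len(motif) - 1 - focal_offset
    hits: set[int] = set()
    for m in re.finditer(f"(?=({fwd}))", seq):
        hits.add(m.start() + focal_offset + 1)
    for m in re.finditer(f"(?=({rev}))", seq):
        hits.add(m.start() + rc_offset + 1)
    return np.array(sorted(hits), dtype=np.int64)


def _peak_membership(positions: np.ndarray, peaks) -> np.ndarray:
    """Boolean mask: which positions fall inside any peak interval."""
    mask = np.zeros(len(positions), dtype=bool)
    for pk in peaks:
        mask |= (positions >= pk.start) & (positions <= pk.end)
    return mask


def aid_motif_enrichment(
    cohort: Cohort,
    peaks,
    reference,
    motif: str = AID_MOTIF,
    focal_offset: int = AID_FOCAL_OFFSET,
) -> dict:
    """Are in-peak mutations enriched at AID-motif focal bases?

    Each pooled mutation event is classified as motif-hit (its position is
    the C of a WRCY match on either strand, equivalently the G of RGYW on
    the forward strand) and as inside/outside the peaks of its chromosome.
    Returns the 2x2 table, the sample odds ratio, the one-sided
    (enrichment) and two-sided Fisher p-values.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    counts = np.zeros((2, 2), dtype=np.int64)  # rows: hit / no-hit; cols: in / out
    for chrom, (pos, _lab) in cohort.pooled.items():
        seq = str(reference[chrom][:])
        focal = motif_focal_positions(seq, motif, focal_offset)
        is_hit = np.isin(pos, focal)
        chrom_peaks = [pk for pk in peaks if pk.chromosome == chrom]
        in_peak = _peak_membership(pos, chrom_peaks)
        counts[0, 0] += int(np.sum(is_hit & in_peak))
        counts[0, 1] += int(np.sum(is_hit & ~in_peak))
        counts[1, 0] += int(np.sum(~is_hit & in_peak))
        counts[1, 1] += int(np.sum(~is_hit & ~in_peak))
    table = Contingency2x2(*counts.flatten().tolist())
    odds, p_two = fisher_exact_2x2(table)
    _, p_greater = fisher_exact_2x2(table, alternative="greater")
    return {
        "table": table,
        "odds_ratio": odds,
        "p_one_sided": p_greater,
        "p_two_sided": p_two,
    }


def peak_group_association(
    cohort: Cohort,
    peaks,
    labels: dict[str, str],
) -> pd.DataFrame:
    """Per-peak association between mutation status and a binary subgroup.

    A patient counts as mutated in a peak if at least one of their
    mutations lies inside the interval. Each peak gets a two-sided Fisher
    p on the patient-level 2x2 table and a BH q across peaks, plus the
    direction of enrichment.
    """
    levels = sorted(set(labels.values()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two subgroup labels, got {levels}")
    labelled = [p for p in cohort.patients if p in labels]
    dropped = len(cohort.patients) - len(labelled)
    if dropped:
        warnings.warn(f"dropping {dropped} unlabelled patients")
    group_a = [p for p in labelled if labels[p] == levels[0]]
    group_b = [p for p in labelled if labels[p] == levels[1]]
    if not group_a or not group_b:
        raise ValueError("one subgroup is empty")

    rows = []
    pvals = []
    for pk in peaks:
        mutated = {
            p
            for p in labelled
            if np.any(
                (cohort.patient_positions(p, pk.chromosome) >= pk.start)
                & (cohort.patient_positions(p, pk.chromosome) <= pk.end)
            )
        }
        a_mut = sum(1 for p in group_a if p in mutated)
        b_mut = sum(1 for p in group_b if p in mutated)
        table = Contingency2x2(
            a_mut, len(group_a) - a_mut, b_mut, len(group_b) - b_mut
        )
        odds, p = fisher_exact_2x2(table)
        frac_a = a_mut / len(group_a)
        frac_b = b_mut / len(group_b)
        direction = levels[0] if frac_a > frac_b else levels[1] if frac_b > frac_a else "none"
        pvals.append(p)
        rows.append(
            {
                "chromosome": pk.chromosome,
                "start": pk.start,
                "end": pk.end,
                f"mutated_{levels[0]}": a_mut,
                f"total_{levels[0]}": len(group_a),
                f"mutated_{levels[1]}": b_mut,
                f"total_{levels[1]}": len(group_b),
                "odds_ratio": odds,
                "p": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(pvals)
    return df


def allelic_imbalance_test(
    records: list[AICountRecord],
    min_coverage: int = 12,
    q_threshold: float = 0.1,
) -> list[AICountRecord]:
    """Test each site's RNA allele balance against its DNA balance.

    Sites where either assay has total coverage below ``min_coverage``
    (default 12x) are excluded before testing. Each remaining site gets a
    two-sided Fisher exact p on [[dna_ref, dna_alt], [rna_ref, rna_alt]],
    a BH q across tested sites, a significance flag (q < ``q_threshold``,
    default 0.1) and the direction of imbalance from comparing the RNA alt
    fraction with the DNA alt fraction.
    """
    tested = [
        r
        for r in records
        if (r.dna_ref + r.dna_alt) >= min_coverage
        and (r.rna_ref + r.rna_alt) >= min_coverage
    ]
    if not tested:
        warnings.warn("all records removed by the coverage filter")
        return []
    pvals = []
    for r in tested:
        _, p = fisher_exact_2x2(
            Contingency2x2(r.dna_ref, r.dna_alt, r.rna_ref, r.rna_alt)
        )
        pvals.append(p)
    qvals = bh_adjust(pvals)
    out = []
    for r, p, q in zip(tested, pvals, qvals):
        dna_frac = r.dna_alt / (r.dna_ref + r.dna_alt)
        rna_frac = r.rna_alt / (r.rna_ref + r.rna_alt)
        sig = q < q_threshold
        if not sig or rna_frac == dna_frac:
            direction = AIDirection.NONE
        elif rna_frac > dna_frac:
            direction = AIDirection.FAVOURS_ALT
        else:
            direction = AIDirection.FAVOURS_REF
        out.append(replace(r, p=p, q=q, significant=sig, direction=direction))
    return out


def ai_patient_ratio(records: list[AICountRecord]) -> pd.DataFrame:
    """Per-gene ratio of patients with allelic imbalance.

    For each gene: the number of distinct patients with at least one
    significant somatic AI record, over the number of distinct patients
    with at least one tested somatic record. Genes with zero tested
    patients are omitted.
    """
    per_gene: dict[str, tuple[set, set]] = {}
    for r in records:
        if not r.is_somatic or r.p is None:
            continue
        ai, tested = per_gene.setdefault(r.gene, (set(), set()))
        tested.add(r.patient_id)
        if r.significant:
            ai.add(r.patient_id)
    rows = [
        {
            "gene": gene,
            "n_ai_patients": len(ai),
            "n_mutated_patients": len(tested),
            "ratio": len(ai) / len(tested),
        }
        for gene, (ai, tested) in sorted(per_gene.items())
        if tested
    ]
    return pd.DataFrame(rows)


def read_ai_counts(path: str) -> list[AICountRecord]:
    """Read per-site DNA/RNA allele counts from TSV (columns: patient,
    gene, chrom, pos, dna_ref, dna_alt, rna_ref, rna_alt, is_somatic)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["patient", "gene", "chrom", "pos",
                "dna_ref", "dna_alt", "rna_ref", "rna_alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: AI counts TSV missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AICountRecord(
                patient_id=str(row.patient),
                gene=str(row.gene),
                chromosome=str(row.chrom),
                position=int(row.pos),
                dna_ref=int(row.dna_ref),
                dna_alt=int(row.dna_alt),
                rna_ref=int(row.rna_ref),
                rna_alt=int(row.rna_alt),
                is_somatic=bool(getattr(row, "is_somatic", True)),
            )
        )
    return out
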