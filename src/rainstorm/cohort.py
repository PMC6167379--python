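"""Cohort assembly and standard-format I/O.

Reads cohort somatic mutation calls (MAF, or per-sample VCF), chromosome
lengths (FAI-style tables) and genomic intervals (BED / GFF3), builds the
in-memory cohort representation used by the rainstorm/doppler pipeline, and
writes all result tables.

Coordinate conventions: 1-based inclusive internally (the MAF convention);
BED output is 0-based half-open. Chromosome names have any leading "chr"
prefix stripped on input so that MAF, BED and FASTA sources interoperate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "VariantClass",
    "MutationRecord",
    "IntervalSet",
    "Cohort",
    "MafFormatError",
    "read_maf",
    "records_from_vcf",
    "read_chrom_lengths",
    "read_bed",
    "read_gff3_intervals",
    "build_cohort",
    "read_points",
    "write_points",
    "write_peaks",
    "read_peaks_bed",
]

# Required MAF columns (standard names, case-sensitive as in the format spec).
MAF_REQUIRED = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


class MafFormatError(ValueError):
    """Raised for malformed MAF / TSV inputs."""


class VariantClass(enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    OTHER = "OTHER"


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix; chromosome names are otherwise kept."""
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class MutationRecord:
    """One simple somatic mutation (SNV or indel) from one patient."""

    patient_id: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass = VariantClass.OTHER
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if self.variant_class is VariantClass.SNV and self.ref_allele == self.alt_allele:
            raise ValueError("SNV must change the base")


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Derive the variant class from allele lengths (MAF uses '-' for gaps)."""
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    bases = set("ACGT")
    if len(ref) == 1 and len(alt) == 1 and ref in bases and alt in bases:
        return VariantClass.SNV
    if ref == "-" or (len(alt) > len(ref)):
        return VariantClass.INS
    if alt == "-" or (len(ref) > len(alt)):
        return VariantClass.DEL
    return VariantClass.OTHER


@dataclass
class IntervalSet:
    """Named genomic intervals (1-based inclusive) with overlap queries."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end, _name in self.intervals:
            if start > end:
                raise ValueError(f"interval start > end on {chrom}: {start} > {end}")
        self._rebuild()

    def _rebuild(self) -> None:
        self._trees = {}
        for chrom, start, end, name in self.intervals:
            # IntervalTree is half-open; +1 makes [start, end] inclusive.
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, name)

    def add(self, chrom: str, start: int, end: int, name: str = ".") -> None:
        if start > end:
            raise ValueError("interval start > end")
        self.intervals.append((chrom, start, end, name))
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, name)

    def overlapping(self, chrom: str, position: int) -> list[str]:
        """Names of intervals covering a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(position))

    def contains(self, chrom: str, position: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(position))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class Cohort:
    """Per-patient sorted mutation positions plus the pooled multiset.

    ``positions[(patient, chromosome)]`` is a strictly increasing int array
    (exact within-patient duplicates are collapsed). ``pooled[chromosome]``
    is the multiset union over patients, stored as a position array sorted
    non-decreasingly with a parallel array of patient indices (indices into
    ``patients``). Cross-patient duplicate positions are kept: the pooled
    set is a multiset.
    """

    patients: list[str]
    positions: dict[tuple[str, str], np.ndarray]
    pooled: dict[str, tuple[np.ndarray, np.ndarray]]
    chrom_lengths: dict[str, int]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def chromosomes(self) -> list[str]:
        return sorted(self.pooled)

    def patient_positions(self, patient_id: str, chromosome: str) -> np.ndarray:
        return self.positions.get((patient_id, chromosome), np.empty(0, dtype=np.int64))

    def patient_total(self, patient_id: str) -> int:
        """Genome-wide mutation count |P_q| for one patient."""
        return int(
            sum(len(v) for (pid, _c), v in self.positions.items() if pid == patient_id)
        )

    def to_records(self) -> list[MutationRecord]:
        """Flatten back to minimal records (alleles are not retained)."""
        out = []
        for (pid, chrom), pos in sorted(self.positions.items()):
            for p in pos:
                out.append(
                    MutationRecord(pid, chrom, int(p), "N", "A", VariantClass.OTHER)
                )
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_maf(path: str | Path, min_fields_policy: str = "strict") -> list[MutationRecord]:
    """Parse a MAF file into mutation records.

    ``min_fields_policy`` controls rows with unparseable positions:
    ``"strict"`` raises a row error naming the line; ``"skip"`` drops them.
    Comment lines (leading ``#``) are skipped. The optional
    ``Variant_Classification`` column, when present, is carried through as
    ``region_label`` (e.g. Intron, 5'Flank).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise MafFormatError(f"MAF file {path} is missing required column {col!r}")
    records: list[MutationRecord] = []
    has_vc = "Variant_Classification" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_pos = getattr(row, "Start_Position")
        try:
            pos = int(float(raw_pos))
        except (TypeError, ValueError):
            if min_fields_policy == "skip":
                continue
            raise MafFormatError(
                f"{path}: unparseable Start_Position {raw_pos!r} at line {i}"
            ) from None
        ref = getattr(row, "Reference_Allele")
        alt = getattr(row, "Tumor_Seq_Allele2")
        records.append(
            MutationRecord(
                patient_id=str(getattr(row, "Tumor_Sample_Barcode")),
                chromosome=normalize_chrom(getattr(row, "Chromosome")),
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_class=classify_variant(ref, alt),
                region_label=getattr(row, "Variant_Classification") if has_vc else None,
            )
        )
    return records


def records_from_vcf(path: str | Path, patient_id: str) -> list[MutationRecord]:
    """Convert one per-sample VCF into mutation records for ``patient_id``.

    Multi-allelic sites contribute one record per ALT allele.
    """
    from cyvcf2 import VCF

    records: list[MutationRecord] = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            records.append(
                MutationRecord(
                    patient_id=patient_id,
                    chromosome=normalize_chrom(v.CHROM),
                    position=int(v.POS),
                    ref_allele=v.REF,
                    alt_allele=alt,
                    variant_class=classify_variant(v.REF, alt),
                )
            )
    return records


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a FAI-style table: first column name, second column length."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise MafFormatError(f"{path}: expected at least two tab-separated columns")
    return {
        normalize_chrom(n): int(l) for n, l in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    ivs: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = normalize_chrom(parts[0])
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            ivs.append((chrom, start + 1, end, name))
    return IntervalSet(ivs)


def read_gff3_intervals(path: str | Path, feature_types: Sequence[str] = ("CDS",)) -> IntervalSet:
    """Extract intervals of given feature types from a GFF3 file.

    GFF3 is 1-based inclusive already. Interval names are taken from the
    gene/Name/ID attributes when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    ivs: list[tuple[str, int, int, str]] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            name = (
                feat.attributes.get("gene_name", [None])[0]
                or feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("ID", ["."])[0]
            )
            ivs.append((normalize_chrom(feat.seqid), feat.start, feat.end, name))
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def build_cohort(
    records: Iterable[MutationRecord],
    chrom_lengths: Mapping[str, int],
    exclude_coding: bool = False,
    coding: IntervalSet | None = None,
    snv_only: bool = False,
) -> Cohort:
    """Assemble the cohort data model from mutation records.

    Positions are sorted per (patient, chromosome) and exact within-patient
    duplicates collapsed; the pooled multiset keeps cross-patient duplicates.
    ``exclude_coding`` drops records whose position falls in any interval of
    ``coding``; ``snv_only`` restricts to SNVs (the signature module needs
    this; the rainstorm statistic accepts all simple somatic mutations).
    """
    if exclude_coding and coding is None:
        raise ValueError("exclude_coding requires a coding IntervalSet")
    chrom_lengths = {normalize_chrom(c): int(l) for c, l in chrom_lengths.items()}

    per: dict[tuple[str, str], set[int]] = {}
    patients: list[str] = []
    seen_patients: set[str] = set()
    for rec in records:
        if snv_only and rec.variant_class is not VariantClass.SNV:
            continue
        chrom = normalize_chrom(rec.chromosome)
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} absent from chrom_lengths")
        if rec.position > chrom_lengths[chrom]:
            raise ValueError(
                f"position {rec.position} exceeds length of chromosome {chrom}"
            )
        if exclude_coding and coding is not None and coding.contains(chrom, rec.position):
            continue
        if rec.patient_id not in seen_patients:
            seen_patients.add(rec.patient_id)
            patients.append(rec.patient_id)
        per.setdefault((rec.patient_id, chrom), set()).add(rec.position)

    patients = sorted(patients)
    pidx = {p: i for i, p in enumerate(patients)}
    positions = {
        key: np.array(sorted(vals), dtype=np.int64) for key, vals in per.items()
    }

    pooled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = sorted({c for (_p, c) in positions})
    for chrom in chroms:
        pos_parts, lab_parts = [], []
        for p in patients:
            arr = positions.get((p, chrom))
            if arr is not None and len(arr):
                pos_parts.append(arr)
                lab_parts.append(np.full(len(arr), pidx[p], dtype=np.int64))
        allpos = np.concatenate(pos_parts)
        alllab = np.concatenate(lab_parts)
        order = np.argsort(allpos, kind="stable")  # stable: ties keep patient order
        pooled[chrom] = (allpos[order], alllab[order])

    return Cohort(
        patients=patients,
        positions=positions,
        pooled=pooled,
        chrom_lengths=chrom_lengths,
    )


# ---------------------------------------------------------------------------
# result-table writers / readers
# ---------------------------------------------------------------------------

POINTS_COLUMNS = ["chromosome", "position", "patient_id", "R"]


def write_points(points, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write rainstorm points as TSV; R is kept to 17 significant digits so a
    write->read round trip is exact."""
    df = points.to_frame()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(POINTS_COLUMNS) + "\n")
        for chrom, pos, pid, r in zip(
            df["chromosome"], df["position"], df["patient_id"], df["R"]
        ):
            fh.write(f"{chrom}\t{pos}\t{pid}\t{r:.17g}\n")


def read_points(path: str | Path):
    """Read a points TSV written by :func:`write_points`."""
    from .distance import RainstormPoints

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in POINTS_COLUMNS if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: points TSV missing columns {missing}")
    try:
        positions = df["position"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise MafFormatError(f"{path}: unparseable position field: {exc}") from None
    r_vals = np.empty(len(df))
    for i, raw in enumerate(df["R"]):
        try:
            r_vals[i] = float(raw)
        except ValueError:
            raise MafFormatError(
                f"{path}: non-numeric R value {raw!r} at data row {i + 1}"
            ) from None
    patients = sorted(df["patient_id"].unique())
    pidx = {p: i for i, p in enumerate(patients)}
    chroms = df["chromosome"].unique()
    if len(chroms) > 1:
        raise MafFormatError("a points file holds a single chromosome")
    chrom = str(chroms[0]) if len(chroms) else ""
    return RainstormPoints(
        chromosome=chrom,
        positions=positions,
        patient_index=df["patient_id"].map(pidx).to_numpy(dtype=np.int64),
        R=r_vals,
        patients=patients,
    )


PEAK_TSV_COLUMNS = [
    "chromosome", "start", "end", "n_mutations", "g_peak", "m_rate",
    "mean_D", "retained", "gene", "region",
]


def write_peaks(peaks, path: str | Path, format: str = "TSV",
                header_lines: Sequence[str] = ()) -> None:
    """Write doppler peaks as TSV (all metrics) or BED (0-based half-open)."""
    fmt = format.upper()
    if fmt not in ("TSV", "BED"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        if fmt == "TSV":
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("\t".join(PEAK_TSV_COLUMNS) + "\n")
            for pk in peaks:
                fh.write(
                    f"{pk.chromosome}\t{pk.start}\t{pk.end}\t{pk.n_mutations}\t"
                    f"{pk.g_peak}\t{pk.m_rate:.6g}\t{pk.mean_D:.6g}\t"
                    f"{int(pk.retained)}\t{pk.gene or '.'}\t{pk.region or '.'}\n"
                )
        else:
            for pk in peaks:
                name = pk.gene or "."
                fh.write(f"{pk.chromosome}\t{pk.start - 1}\t{pk.end}\t{name}\n")


def read_peaks_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read peak intervals back from BED as (chrom, start, end) 1-based."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2]), parts[3]))
    return out
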