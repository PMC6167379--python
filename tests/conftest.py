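import numpy as np
import pytest

from rainstorm import MutationRecord, VariantClass, build_cohort


MAF_HEADER = (
    "Tumor_Sample_Barcode\tChromosome\tStart_Position\t"
    "Reference_Allele\tTumor_Seq_Allele2\n"
)


def make_maf(path, rows):
    """Write a minimal MAF file from (patient, chrom, pos, ref, alt) rows."""
    with open(path, "w") as fh:
        fh.write(MAF_HEADER)
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


def snv(patient, chrom, pos, ref="C", alt="T"):
    return MutationRecord(patient, chrom, pos, ref, alt, VariantClass.SNV)


@pytest.fixture
def toy_cohort():
    """Six patients on one 1 Mb chromosome with hand-placed positions."""
    positions = {
        "A": [1000, 5000, 200000],
        "B": [1200, 90000, 500000],
        "C": [3000, 91000, 500010],
        "D": [50000, 92000, 700000],
        "E": [1500, 400000, 900000],
        "F": [2500, 93000, 910000],
    }
    records = [
        snv(p, "1", pos) for p, plist in positions.items() for pos in plist
    ]
    return build_cohort(records, {"1": 1_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
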