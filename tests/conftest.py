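import numpy as np
import pandas as pd
import pytest

from riboscreen.design import LibraryDesign, SpikeIn, SubLibrary, builtin_design


@pytest.fixture
def toy_design() -> LibraryDesign:
    """Single 3N sub-library, 64 variants."""
    return builtin_design("toy")


@pytest.fixture
def two_sub_design() -> LibraryDesign:
    """Two sub-libraries with distinct fixed cores and disjoint N-runs."""
    return LibraryDesign(
        name="two-sub",
        sub_libraries=(
            SubLibrary("s5", "GGA" + "NN" + "TACGT" + "NNN" + "CCT"),
            SubLibrary("s6", "GGA" + "NNN" + "CGTAC" + "NNN" + "CCT"),
        ),
        flank_5p="CATTGCAGCGTATTCCCAGTCC",
        flank_3p="GCCTGGTGAAATTGTTATCCGCT",
        spacer="CAAACAAA",
        spike_in=SpikeIn("sp1", "CATTGCAGCGTATTCCCAGTCC" + "CAAACAAA"
                         + "TTGACGGCTAGCTCAGTCCTAGG" + "CAAACAAA"
                         + "GCCTGGTGAAATTGTTATCCGCT"),
    )


def write_fastq(path, reads):
    """Write plain FASTQ with constant qualities."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


@pytest.fixture
def fastq_writer():
    return write_fastq


def make_samplesheet(doses, replicates):
    rows = [
        {"sample": f"d{d:g}_r{r + 1}", "dose_uM": float(d), "replicate": r + 1}
        for d in doses
        for r in range(replicates)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def samplesheet_factory():
    return make_samplesheet
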