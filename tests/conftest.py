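import textwrap

import pytest

from mirseq.catalog import Catalog, MatureMiRNA

# A 3'-adapter used by crafted FASTQ fixtures (first 8 nt are the search key).
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture
def tiny_catalog() -> Catalog:
    """Three hand-picked mature sequences, two of which share a sequence (family)."""
    return Catalog(
        entries=[
            MatureMiRNA("mir-alpha", "TGGAATGTAAAGAAGTATGTAT"),
            MatureMiRNA("mir-beta", "ACGTACGTACGTACGTACGTAC"),
            MatureMiRNA("mir-beta-family", "ACGTACGTACGTACGTACGTAC"),
            MatureMiRNA("mir-gamma", "CCTTGGAGTAAAGTAGCAGCACAT"),
        ],
        source="test fixture",
    )


def write_fastq(path, records):
    """records: iterable of (name, seq, qual); qual may be None for constant I."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if qual is None:
                qual = "I" * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


@pytest.fixture
def fastq_writer(tmp_path):
    def _write(records, name="reads.fastq"):
        return write_fastq(tmp_path / name, records)

    return _write
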