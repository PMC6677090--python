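"""Read cleaning, tag collapsing and library-level summaries.

Raw small-RNA reads carry adapter sequence and assorted junk (homopolymer runs,
N-containing reads, adapter dimers, low-quality reads).  Cleaning removes these with a
fixed rule precedence so that every read is claimed by exactly one removal category and
the report is a partition of the raw reads — a conservation law the tests enforce on
arbitrary inputs.  Clean reads are then collapsed into unique *tags* with counts, the
unit all downstream quantification consumes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_HOMOPOLYMER_FRAC = 0.8
DEFAULT_MIN_MEAN_Q = 20.0

#: Removal categories, in rule-precedence order.
REMOVAL_CATEGORIES = (
    "removed_low_quality",
    "removed_polyN",
    "removed_5adapter",
    "removed_no3adapter",
    "removed_polyACGT",
    "removed_length",
)


class FastqFormatError(ValueError):
    """Raised when a FASTQ record cannot be parsed."""


@dataclass
class CleaningReport:
    """Per-category removal counts; categories + clean reads partition raw reads."""

    raw_reads: int = 0
    removed_low_quality: int = 0
    removed_polyN: int = 0
    removed_5adapter: int = 0
    removed_no3adapter: int = 0
    removed_polyACGT: int = 0
    removed_length: int = 0
    clean_reads: int = 0

    def removed_total(self) -> int:
        return sum(getattr(self, c) for c in REMOVAL_CATEGORIES)

    def check_conservation(self) -> None:
        if self.raw_reads != self.clean_reads + self.removed_total():
            raise AssertionError(
                f"cleaning report does not balance: raw={self.raw_reads}, "
                f"clean={self.clean_reads}, removed={self.removed_total()}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("raw_reads", self.raw_reads)]
        rows += [(c, getattr(self, c)) for c in REMOVAL_CATEGORIES]
        rows.append(("clean_reads", self.clean_reads))
        return pd.DataFrame(rows, columns=["category", "reads"])


@dataclass
class TagSet:
    """Collapsed unique tag sequences with counts for one library."""

    counts: dict[str, int] = field(default_factory=dict)
    library_label: str = ""

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, tag: str) -> bool:
        return tag in self.counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tag": list(self.counts), "count": list(self.counts.values())}
        )

    def write_fasta(self, path) -> None:
        """Collapsed-tag FASTA, header dialect ``>t{serial}_x{count}``."""
        with open(path, "w") as fh:
            for i, (tag, count) in enumerate(self.counts.items(), start=1):
                fh.write(f">t{i}_x{count}\n{tag}\n")


@dataclass
class LibraryComparison:
    """Tag overlap between two libraries (the common/specific split of a Venn)."""

    common_unique: int
    a_specific_unique: int
    b_specific_unique: int
    common_total: int
    a_specific_total: int
    b_specific_total: int

    @property
    def grand_total(self) -> int:
        return self.common_total + self.a_specific_total + self.b_specific_total

    @property
    def common_total_fraction(self) -> float:
        return self.common_total / self.grand_total if self.grand_total else 0.0

    @property
    def a_specific_total_fraction(self) -> float:
        return self.a_specific_total / self.grand_total if self.grand_total else 0.0

    @property
    def b_specific_total_fraction(self) -> float:
        return self.b_specific_total / self.grand_total if self.grand_total else 0.0


def _mean_quality(qual: str) -> float:
    # Phred+33
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def _is_homopolymer(seq: str, frac: float) -> bool:
    if not seq:
        return False
    top = max(seq.count(b) for b in "ACGT")
    return top >= frac * len(seq)


def clean_reads(
    fastq_path,
    adapter3: Optional[str] = None,
    adapter5: Optional[str] = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    homopolymer_frac: float = DEFAULT_HOMOPOLYMER_FRAC,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
) -> tuple[list[str], CleaningReport]:
    """Filter and adapter-trim a FASTQ file of raw small-RNA reads.

    Rules are applied in a fixed precedence; the first that matches claims the read:

    1. low quality — mean Phred score below ``min_mean_q``;
    2. poly-N — any N in the read;
    3. 5'-adapter contamination — read begins with ``adapter5``;
    4. missing 3' adapter — the first 8 nt of ``adapter3`` do not occur in the read
       (when they do, the read is trimmed at the match to recover the insert);
    5. homopolymer — one base makes up ``homopolymer_frac`` or more of the insert;
    6. length — trimmed insert outside ``[min_len, max_len]`` (the gel-excision
       window of the library prep).

    Either adapter may be ``None``, in which case its rule is skipped — simulated
    libraries are written insert-only.  Returns the surviving trimmed inserts
    (upper-cased) and a :class:`CleaningReport`.
    """
    report = CleaningReport()
    survivors: list[str] = []
    adapter3_key = adapter3[:8].upper() if adapter3 else None
    adapter5 = adapter5.upper() if adapter5 else None

    try:
        with open(fastq_path) as handle:
            for idx, (_title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                report.raw_reads += 1
                seq = seq.upper()
                if len(seq) != len(qual):
                    raise FastqFormatError(
                        f"record {idx}: sequence/quality length mismatch"
                    )
                if _mean_quality(qual) < min_mean_q:
                    report.removed_low_quality += 1
                    continue
                if "N" in seq:
                    report.removed_polyN += 1
                    continue
                if adapter5 and seq.startswith(adapter5):
                    report.removed_5adapter += 1
                    continue
                insert = seq
                if adapter3_key is not None:
                    pos = seq.find(adapter3_key)
                    if pos < 0:
                        report.removed_no3adapter += 1
                        continue
                    insert = seq[:pos]
                if _is_homopolymer(insert, homopolymer_frac):
                    report.removed_polyACGT += 1
                    continue
                if not (min_len <= len(insert) <= max_len):
                    report.removed_length += 1
                    continue
                report.clean_reads += 1
                survivors.append(insert)
    except ValueError as exc:
        if isinstance(exc, FastqFormatError):
            raise
        raise FastqFormatError(
            f"malformed FASTQ near record {report.raw_reads}: {exc}"
        ) from exc

    report.check_conservation()
    return survivors, report


def collapse_tags(reads: Iterable[str], library_label: str = "") -> TagSet:
    """Merge identical read sequences into counted unique tags."""
    return TagSet(counts=dict(Counter(reads)), library_label=library_label)


def length_distribution(tags: TagSet) -> pd.DataFrame:
    """Read-count distribution over tag length; fractions are of total reads.

    Small-RNA libraries dominated by miRNA peak at 22 nt — the diagnostic this table
    exists to show.
    """
    if tags.total_reads == 0:
        raise ValueError("length distribution of an empty tag set is undefined")
    per_len: Counter[int] = Counter()
    for tag, count in tags.counts.items():
        per_len[len(tag)] += count
    total = tags.total_reads
    lengths = sorted(per_len)
    return pd.DataFrame(
        {
            "length": lengths,
            "reads": [per_len[l] for l in lengths],
            "fraction": [per_len[l] / total for l in lengths],
        }
    )


def compare_libraries(a: TagSet, b: TagSet) -> LibraryComparison:
    """Partition tags of two libraries into common and library-specific sets.

    A tag is *common* iff present in both libraries; its total contribution is the sum
    of its counts in A and B, so the three total-read categories partition
    ``total_reads(A) + total_reads(B)``.
    """
    a_tags, b_tags = set(a.counts), set(b.counts)
    common = a_tags & b_tags
    return LibraryComparison(
        common_unique=len(common),
        a_specific_unique=len(a_tags - b_tags),
        b_specific_unique=len(b_tags - a_tags),
        common_total=sum(a.counts[t] for t in common) + sum(b.counts[t] for t in common),
        a_specific_total=sum(a.counts[t] for t in a_tags - b_tags),
        b_specific_total=sum(b.counts[t] for t in b_tags - a_tags),
    )
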