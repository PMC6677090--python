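"""Tag-to-miRNA assignment by exact sequence match, counting, and TPM normalization.

Assignment is exact full-sequence identity (the zero-mismatch criterion): a hash
lookup against the catalog.  Tags matching no catalog entry form the *unannotated*
pool that the variant profiler consumes.  Tags whose sequence is shared by several
catalog entries (miRNA families) count fully toward each — any fractional split would
be arbitrary — and are flagged as multimapped in the output.

TPM here is tags per million: count / total clean reads x 1e6.  The denominator is
the library's total clean-read count, not the miRNA-assigned subtotal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import Catalog
from .preprocess import TagSet

TPM_SCALE = 1_000_000


@dataclass
class TagAssignment:
    """tag sequence -> list of matched miRNA names (empty = unannotated)."""

    matches: dict[str, list[str]] = field(default_factory=dict)
    source_label: str = ""
    source_n_tags: int = 0

    def multimapped(self) -> dict[str, list[str]]:
        return {t: ms for t, ms in self.matches.items() if len(ms) > 1}

    def unannotated(self, tags: TagSet) -> TagSet:
        """The tags that matched nothing, with their counts preserved."""
        return TagSet(
            counts={t: c for t, c in tags.counts.items() if not self.matches[t]},
            library_label=tags.library_label,
        )


@dataclass
class ExpressionProfile:
    """Per-miRNA raw count and TPM for one library."""

    counts: dict[str, int]
    tpm: dict[str, float]
    library_total_clean_reads: int
    library_label: str = ""
    multimap_note: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.counts)
        return pd.DataFrame(
            {
                "mirna": names,
                "count": [self.counts[n] for n in names],
                "tpm": [self.tpm[n] for n in names],
                "multimap_note": [self.multimap_note.get(n, ".") for n in names],
            }
        )


def match_tags(tags: TagSet, catalog: Catalog) -> TagAssignment:
    """Assign each tag to every catalog miRNA with the identical mature sequence."""
    if len(catalog) == 0:
        raise ValueError("cannot match tags against an empty catalog")
    by_seq: dict[str, list[str]] = {}
    for entry in catalog:
        by_seq.setdefault(entry.sequence, []).append(entry.name)
    return TagAssignment(
        matches={t: list(by_seq.get(t, [])) for t in tags.counts},
        source_label=tags.library_label,
        source_n_tags=len(tags),
    )


def count_mirnas(
    assignment: TagAssignment, tags: TagSet, catalog: Catalog
) -> dict[str, int]:
    """Sum matched tag counts per miRNA; unmatched catalog entries get count 0.

    Zero counts are reported, not dropped: a miRNA absent from one library but
    present in the other is the "specifically expressed" case the differential
    stage must see.
    """
    if (
        assignment.source_label != tags.library_label
        or assignment.source_n_tags != len(tags)
    ):
        raise ValueError(
            "assignment was not built from this TagSet "
            f"(assignment: {assignment.source_label!r}/{assignment.source_n_tags} tags,"
            f" tags: {tags.library_label!r}/{len(tags)} tags)"
        )
    counts = {name: 0 for name in catalog.names()}
    for tag, mirnas in assignment.matches.items():
        c = tags.counts[tag]
        for name in mirnas:
            counts[name] += c
    return counts


def tpm_normalize(
    counts: dict[str, int],
    n_clean_reads: int,
    library_label: str = "",
    catalog: Catalog | None = None,
) -> ExpressionProfile:
    """Normalize counts to tags per million of total clean reads."""
    if n_clean_reads <= 0:
        raise ValueError(f"library clean-read total must be positive, got {n_clean_reads}")
    tpm = {m: c / n_clean_reads * TPM_SCALE for m, c in counts.items()}
    note: dict[str, str] = {}
    if catalog is not None:
        for entry in catalog:
            if entry.shared_sequence and entry.name in counts:
                note[entry.name] = "shared_mature_sequence"
    return ExpressionProfile(
        counts=dict(counts),
        tpm=tpm,
        library_total_clean_reads=n_clean_reads,
        library_label=library_label,
        multimap_note=note,
    )


def quantify_library(
    tags: TagSet, catalog: Catalog, n_clean_reads: int | None = None
) -> tuple[ExpressionProfile, TagSet]:
    """Convenience pipeline: match, count, normalize; returns (profile, unannotated).

    ``n_clean_reads`` defaults to the tag set's own total, which is correct when the
    tag set holds every clean read of the library.
    """
    assignment = match_tags(tags, catalog)
    counts = count_mirnas(assignment, tags, catalog)
    n = tags.total_reads if n_clean_reads is None else n_clean_reads
    profile = tpm_normalize(counts, n, tags.library_label, catalog)
    return profile, assignment.unannotated(tags)
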