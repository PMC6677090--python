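"""Mature-miRNA catalog: the sequence reference every other stage matches against.

Catalogs follow the miRBase mature-FASTA dialect (RNA alphabet, whitespace-delimited
headers whose first token is the miRNA name, e.g. ``ssc-miR-206``).  All sequences are
held internally in the DNA alphabet (U converted to T on load) because sequenced tags
are DNA; coordinates in every user-facing report are 1-based inclusive, so the seed
region is "positions 2-8" exactly as the field writes it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = "ACGT"
#: Seed region of a mature miRNA: positions 2-8, 1-based inclusive.
SEED_START, SEED_END = 2, 8

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 30


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog input."""


@dataclass
class MatureMiRNA:
    """A named mature miRNA sequence.

    ``shared_sequence`` is set by :class:`Catalog` when another entry carries the
    identical sequence (miRNA families such as let-7 genuinely do).
    """

    name: str
    sequence: str
    shared_sequence: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise CatalogError(f"{self.name}: empty sequence")
        bad = set(seq) - set(DNA_BASES + "N")
        if bad:
            raise CatalogError(f"{self.name}: invalid characters {sorted(bad)!r}")
        if "N" in seq:
            raise CatalogError(f"{self.name}: sequence contains N")
        if not (MIN_MATURE_LEN <= len(seq) <= MAX_MATURE_LEN):
            raise CatalogError(
                f"{self.name}: length {len(seq)} outside "
                f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
            )
        self.sequence = seq

    @property
    def seed(self) -> str:
        """The 7-mer at positions 2-8 (1-based); derived, never stored."""
        return seed_of(self)


def seed_of(m: "MatureMiRNA | str") -> str:
    """Return positions 2-8 (1-based inclusive) of a mature sequence.

    Single substitutions in this 7-mer ("seed edits") can retarget the miRNA, which
    is why the region gets dedicated treatment downstream.
    """
    seq = m.sequence if isinstance(m, MatureMiRNA) else m
    if len(seq) < SEED_END:
        raise CatalogError(f"sequence of length {len(seq)} has no full seed region")
    return seq[SEED_START - 1 : SEED_END]


@dataclass
class Catalog:
    """Ordered collection of :class:`MatureMiRNA` with unique names."""

    entries: list[MatureMiRNA] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise CatalogError(f"duplicate miRNA name: {n!r}")
            seen.add(n)
        self._flag_shared()
        self._by_name = {e.name: e for e in self.entries}

    def _flag_shared(self) -> None:
        by_seq: dict[str, list[MatureMiRNA]] = {}
        for e in self.entries:
            by_seq.setdefault(e.sequence, []).append(e)
        for group in by_seq.values():
            if len(group) > 1:
                for e in group:
                    e.shared_sequence = True

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MatureMiRNA]:
        return iter(self.entries)

    def __getitem__(self, name: str) -> MatureMiRNA:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def sequences_by_name(self) -> dict[str, str]:
        return {e.name: e.sequence for e in self.entries}


def load_mature_fasta(path, species_prefix: Optional[str] = None) -> Catalog:
    """Load a mature-miRNA FASTA catalog.

    Sequences are upper-cased and U->T converted; records containing N are rejected.
    If ``species_prefix`` is given (e.g. ``"ssc"``) only names starting with it are
    retained; an empty result is a hard error.  File order is preserved.
    """
    entries: list[MatureMiRNA] = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if species_prefix is not None and not name.startswith(species_prefix):
                continue
            entries.append(MatureMiRNA(name=name, sequence=str(record.seq)))
    if not entries:
        suffix = f" with species prefix {species_prefix!r}" if species_prefix else ""
        raise CatalogError(f"no catalog entries loaded from {path!s}{suffix}")
    return Catalog(entries=entries, source=str(path))


def write_fasta(catalog: Catalog, path) -> None:
    """Write a catalog as ``>name`` + single-line sequence; round-trips with load."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.name, description="") for e in catalog
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(records)
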