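"""IsomiR end-variant classification and seed-edit detection.

Mature miRNAs show sequence heterogeneity concentrated at the 3' end: terminal
trimming, non-templated addition, and occasional 5' shifts (isomiRs).  Separately,
single-nucleotide substitutions inside the seed region (positions 2-8) can retarget
a miRNA; candidate seed edits are found by matching *unannotated* tags — tags that
matched no catalog sequence exactly — against the catalog at Hamming distance one.

Detection uses a one-substitution neighborhood index: every mature sequence
contributes L x 3 single-substitution variants to a hash map, so each tag is a single
lookup.  The index is behaviorally identical to an all-pairs scan (the test suite
compares both routes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

import pandas as pd

from .catalog import Catalog, MatureMiRNA, DNA_BASES, SEED_START, SEED_END
from .preprocess import TagSet

CLASS_CANONICAL = "canonical"
CLASS_TRIM3 = "trim3"
CLASS_ADD3 = "add3"
CLASS_SHIFT5 = "shift5"
CLASS_SEED_EDIT = "seed_edit"
CLASS_NONSEED_SUB = "nonseed_sub"

DEFAULT_MIN_COUNT = 5

#: The 12 possible substitutions, ordered for the spectrum table.
SUBSTITUTION_ORDER = [
    (f, t) for f, t in product(DNA_BASES, DNA_BASES) if f != t
]


@dataclass(frozen=True)
class VariantEvent:
    """One isomiR or substitution observation against a mature miRNA.

    ``position`` is 1-based on the mature sequence for substitutions, and a signed
    end offset for end variants (e.g. trim3 of one base = -1, add3 of two = +2).
    """

    mirna_name: str
    variant_class: str
    position: int
    from_base: str
    to_base: str
    tag: str
    count: int


def classify_isomir(tag: str, m: MatureMiRNA) -> Optional[tuple[str, int]]:
    """Classify a tag as an end variant of mature ``m``; None = no call.

    Classes, with precedence trim3 > add3 > shift5:

    - ``trim3``: tag equals the mature with 1-2 terminal 3' bases removed;
    - ``add3``: tag equals the mature plus 1-2 extra 3' bases;
    - ``shift5``: tag starts one base later than the mature, or carries one extra
      5' base, with its 3' end within +/-2 nt of the mature's.

    Returns ``(class, offset)`` where offset is the signed 3' length change for
    trim3/add3 and the signed 5'-start shift for shift5 (+1 = one base prepended).
    Internal mismatches and larger end changes are no-calls; substitution classes are
    handled by :func:`detect_seed_edits`.
    """
    mature = m.sequence
    if tag == mature:
        return (CLASS_CANONICAL, 0)
    for k in (1, 2):
        if len(tag) == len(mature) - k and tag == mature[:-k]:
            return (CLASS_TRIM3, -k)
    for k in (1, 2):
        if len(tag) == len(mature) + k and tag[: len(mature)] == mature:
            return (CLASS_ADD3, k)
    if _is_shift5(tag, mature[1:]):
        return (CLASS_SHIFT5, -1)
    if len(tag) >= 2 and _is_shift5(tag[1:], mature):
        return (CLASS_SHIFT5, +1)
    return None


def _is_shift5(tag: str, core: str) -> bool:
    """tag equals core with its 3' end within +/-2 nt (extra 3' bases unconstrained)."""
    d = len(tag) - len(core)
    if not -2 <= d <= 2:
        return False
    if d <= 0:
        return tag == core[: len(tag)]
    return tag[: len(core)] == core


def _one_substitution_index(
    catalog: Catalog,
) -> dict[str, list[tuple[str, int, str, str]]]:
    """Map every single-substitution variant sequence -> [(mirna, pos, from, to)]."""
    index: dict[str, list[tuple[str, int, str, str]]] = {}
    for entry in catalog:
        seq = entry.sequence
        for i, ref in enumerate(seq):
            for alt in DNA_BASES:
                if alt == ref:
                    continue
                variant = seq[:i] + alt + seq[i + 1 :]
                index.setdefault(variant, []).append(
                    (entry.name, i + 1, ref, alt)
                )
    return index


def detect_seed_edits(
    unannotated: TagSet,
    catalog: Catalog,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[VariantEvent]:
    """Find single-substitution matches of unannotated tags to the catalog.

    A tag yields a ``seed_edit`` event for miRNA m iff it has the mature's length,
    differs at exactly one position, that position lies in the seed (2-8), and the
    tag's count is at least ``min_count``.  One-mismatch tags whose mismatch lies
    outside the seed (position 1, or 9..L) yield ``nonseed_sub`` events — reported,
    but excluded from the substitution spectrum.  A tag matching several miRNAs
    yields one event per miRNA.  Combined length-variant + substitution tags are
    not detected (equal length is required).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    index = _one_substitution_index(catalog)
    events: list[VariantEvent] = []
    for tag, count in unannotated.counts.items():
        if count < min_count:
            continue
        for mirna, pos, ref, alt in index.get(tag, []):
            klass = (
                CLASS_SEED_EDIT
                if SEED_START <= pos <= SEED_END
                else CLASS_NONSEED_SUB
            )
            events.append(
                VariantEvent(
                    mirna_name=mirna,
                    variant_class=klass,
                    position=pos,
                    from_base=ref,
                    to_base=alt,
                    tag=tag,
                    count=count,
                )
            )
    return events


def detect_seed_edits_bruteforce(
    unannotated: TagSet, catalog: Catalog, min_count: int = DEFAULT_MIN_COUNT
) -> list[VariantEvent]:
    """All-pairs Hamming scan; quadratic reference for the neighborhood index."""
    events: list[VariantEvent] = []
    for tag, count in unannotated.counts.items():
        if count < min_count:
            continue
        for entry in catalog:
            seq = entry.sequence
            if len(seq) != len(tag):
                continue
            diffs = [i for i, (a, b) in enumerate(zip(seq, tag)) if a != b]
            if len(diffs) != 1:
                continue
            pos = diffs[0] + 1
            klass = (
                CLASS_SEED_EDIT
                if SEED_START <= pos <= SEED_END
                else CLASS_NONSEED_SUB
            )
            events.append(
                VariantEvent(
                    entry.name, klass, pos, seq[pos - 1], tag[pos - 1], tag, count
                )
            )
    return events


@dataclass
class SubstitutionSpectrum:
    """Counts and percentages over the 12 from->to substitution types."""

    counts: dict[tuple[str, str], int]
    empty: bool

    def to_frame(self) -> pd.DataFrame:
        total = sum(self.counts.values())
        rows = []
        for f, t in SUBSTITUTION_ORDER:
            c = self.counts[(f, t)]
            rows.append(
                {
                    "from": f,
                    "to": t,
                    "events": c,
                    "percent": (100.0 * c / total) if total else 0.0,
                }
            )
        return pd.DataFrame(rows)


def substitution_spectrum(events: Iterable[VariantEvent]) -> SubstitutionSpectrum:
    """Tally seed-edit events by substitution type.

    Each distinct (miRNA, position, from, to) combination counts once — events, not
    reads — so one abundant edit cannot dominate the spectrum.
    """
    distinct = {
        (e.mirna_name, e.position, e.from_base, e.to_base)
        for e in events
        if e.variant_class == CLASS_SEED_EDIT
    }
    counts = Counter((f, t) for _, _, f, t in distinct)
    return SubstitutionSpectrum(
        counts={pair: counts.get(pair, 0) for pair in SUBSTITUTION_ORDER},
        empty=not distinct,
    )


def edited_mirna_count(events: Iterable[VariantEvent]) -> int:
    """Number of distinct miRNAs with at least one seed-edit event."""
    return len(
        {e.mirna_name for e in events if e.variant_class == CLASS_SEED_EDIT}
    )


def classify_unannotated(
    unannotated: TagSet, catalog: Catalog
) -> pd.DataFrame:
    """End-variant profile of the unannotated pool against the whole catalog.

    Returns one row per (tag, miRNA, class) for tags classifiable as trim3/add3/
    shift5 of some catalog entry.
    """
    rows = []
    for tag, count in unannotated.counts.items():
        for entry in catalog:
            call = classify_isomir(tag, entry)
            if call is not None and call[0] != CLASS_CANONICAL:
                rows.append(
                    {
                        "tag": tag,
                        "mirna": entry.name,
                        "class": call[0],
                        "offset": call[1],
                        "count": count,
                    }
                )
    return pd.DataFrame(rows, columns=["tag", "mirna", "class", "offset", "count"])


def events_to_frame(events: Iterable[VariantEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": e.mirna_name,
                "class": e.variant_class,
                "position": e.position,
                "from": e.from_base,
                "to": e.to_base,
                "tag": e.tag,
                "count": e.count,
            }
            for e in events
        ],
        columns=["mirna", "class", "position", "from", "to", "tag", "count"],
    )
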