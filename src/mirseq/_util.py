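"""Shared helpers: deterministic sub-seed derivation and TSV conventions."""

from __future__ import annotations

import hashlib

#: Missing-value marker used in every TSV this package writes.
TSV_NA = "."


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed (< 2**31) from one global seed.

    Stages draw from independent streams so adding a stage never perturbs the
    randomness of the others.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
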