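"""Two-condition small-RNA library simulator with ground truth.

Emulates the statistical structure of a pooled two-library miRNA-seq comparison: a
long-tailed (log-normal) abundance profile over a mature-miRNA catalog, a subset of
miRNAs given a true fold change in condition B, 3'-dominant isomiR variation (terminal
trimming and non-templated addition), rare 5' shifts, rare single-substitution seed
edits, contaminant reads (homopolymer runs, short fragments, random sequence), and
uniform per-base substitution error.  Every stochastic choice is recorded so each
pipeline stage can be checked against known truth.

One library per condition, no replicates — the design the exact conditional count
test is built for.  Reads are generated in collapsed form (sequence -> count), which
keeps simulation at full sequencing depth cheap; FASTQ expansion happens only on
write, with constant Phred-40 quality strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import Catalog, MatureMiRNA, DNA_BASES
from .preprocess import TagSet

TPM_TOTAL = 1_000_000.0

#: geometric(0.5) truncated at 2: length of a 3' trim or addition
_GEOM12 = (2.0 / 3.0, 1.0 / 3.0)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-library comparison.

    Defaults describe the standard comparison the test suite exercises: 300 miRNAs,
    one million reads per pooled library, 10% of miRNAs truly changed four-fold,
    baseline abundance log-normal with sigma 1.5 floored at 50 TPM, modest 3'-dominant
    isomiR rates, rare seed edits, 5% contaminants and a 0.1% per-base error rate.
    """

    n_mirnas: int = 300
    depth_a: int = 1_000_000
    depth_b: int = 1_000_000
    de_fraction: float = 0.1
    effect_log2fc: float = 2.0
    abundance_sigma: float = 1.5
    min_tpm: float = 50.0
    trim3_prob: float = 0.15
    add3_prob: float = 0.05
    shift5_prob: float = 0.02
    seed_edit_rate: float = 0.002
    contaminant_fraction: float = 0.05
    error_rate: float = 0.001
    seed: int = 0
    length_range: tuple[int, int] = (18, 25)

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if self.depth_a < 1 or self.depth_b < 1:
            raise ValueError("library depths must be >= 1")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must lie in [0, 1)")
        probs = {
            "trim3_prob": self.trim3_prob,
            "add3_prob": self.add3_prob,
            "shift5_prob": self.shift5_prob,
            "seed_edit_rate": self.seed_edit_rate,
            "contaminant_fraction": self.contaminant_fraction,
            "error_rate": self.error_rate,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        variant_mass = (
            self.trim3_prob + self.add3_prob + self.shift5_prob + self.seed_edit_rate
        )
        if variant_mass > 1:
            raise ValueError(
                f"variant probabilities sum to {variant_mass} > 1"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        return d


@dataclass
class GroundTruth:
    """Known truth of a simulation: per-miRNA TPM, DE labels, planted variants."""

    table: pd.DataFrame  # mirna, tpm_a, tpm_b, log2fc_true, is_de
    manifest: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["library", "mirna", "position", "from", "to", "count"]
        )
    )
    contaminant_reads: dict[str, int] = field(default_factory=dict)

    def de_names(self) -> set[str]:
        return set(self.table.loc[self.table["is_de"], "mirna"])


def simulate_catalog(
    n: int, length_range: tuple[int, int] = (18, 25), rng: np.random.Generator = None
) -> Catalog:
    """Generate ``n`` unique random mature sequences named sim-mir-001, ..."""
    if n < 1:
        raise ValueError("catalog size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = length_range
    seqs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 100 * n + 1000
    while len(seqs) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {n} unique sequences in {max_attempts} attempts"
            )
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(DNA_BASES), size=length))
        if seq in seen:
            continue
        seen.add(seq)
        seqs.append(seq)
    width = max(3, len(str(n)))
    entries = [
        MatureMiRNA(name=f"sim-mir-{i + 1:0{width}d}", sequence=s)
        for i, s in enumerate(seqs)
    ]
    return Catalog(entries=entries, source=f"simulated n={n}")


def _floor_renormalize(weights: np.ndarray, floor: float) -> np.ndarray:
    """Scale to TPM (sum 1e6) with every entry >= floor, by waterfilling."""
    tpm = weights / weights.sum() * TPM_TOTAL
    if floor <= 0:
        return tpm
    if floor * len(tpm) > TPM_TOTAL:
        raise ValueError("TPM floor infeasible for this catalog size")
    for _ in range(1000):
        low = tpm < floor
        if not low.any():
            break
        tpm[low] = floor
        rest_mass = TPM_TOTAL - floor * low.sum()
        rest = ~low
        tpm[rest] = tpm[rest] / tpm[rest].sum() * rest_mass
    return tpm


def simulate_abundances(
    catalog: Catalog, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw baseline abundances and plant condition-B fold changes.

    Baseline abundance is log-normal(0, ``abundance_sigma``) renormalized to TPM and
    floored at ``min_tpm``.  ``round(de_fraction * n)`` miRNAs receive a
    ``±effect_log2fc`` multiplier (random sign) in condition B before B is
    renormalized; recorded true log2 fold changes are the post-renormalization TPM
    ratios, so non-DE miRNAs carry a small compositional shift when any DE exists.
    """
    config.validate()
    n = len(catalog)
    base = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    tpm_a = _floor_renormalize(base, config.min_tpm)

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    weight_b = tpm_a.copy()
    weight_b[de_idx] *= 2.0 ** (signs * config.effect_log2fc)
    tpm_b = weight_b / weight_b.sum() * TPM_TOTAL

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    table = pd.DataFrame(
        {
            "mirna": catalog.names(),
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "log2fc_true": np.log2(tpm_b / tpm_a),
            "is_de": is_de,
        }
    )
    return GroundTruth(table=table)


def _add(lib: dict[str, int], seq: str, count: int) -> None:
    if count:
        lib[seq] = lib.get(seq, 0) + int(count)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=length))


def _simulate_library(
    catalog: Catalog,
    tpm: np.ndarray,
    depth: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    library: str,
) -> tuple[dict[str, int], list[tuple], int]:
    names = catalog.names()
    seqs = [e.sequence for e in catalog]
    n_contam = int(round(depth * config.contaminant_fraction))
    n_cat = depth - n_contam
    class_probs = np.array(
        [
            1.0
            - config.trim3_prob
            - config.add3_prob
            - config.shift5_prob
            - config.seed_edit_rate,
            config.trim3_prob,
            config.add3_prob,
            config.shift5_prob,
            config.seed_edit_rate,
        ]
    )
    counts = rng.multinomial(n_cat, tpm / tpm.sum())
    lib: dict[str, int] = {}
    manifest: list[tuple] = []
    two_mers = ["".join(p) for p in product(DNA_BASES, repeat=2)]

    for i, c in enumerate(counts):
        if c == 0:
            continue
        seq = seqs[i]
        n_can, n_trim, n_add, n_shift, n_edit = rng.multinomial(c, class_probs)
        _add(lib, seq, n_can)
        if n_trim:
            m1 = rng.binomial(n_trim, _GEOM12[0])
            _add(lib, seq[:-1], m1)
            _add(lib, seq[:-2], n_trim - m1)
        if n_add:
            m1 = rng.binomial(n_add, _GEOM12[0])
            for b, cb in zip(DNA_BASES, rng.multinomial(m1, [0.25] * 4)):
                _add(lib, seq + b, cb)
            for bb, cb in zip(two_mers, rng.multinomial(n_add - m1, [1 / 16] * 16)):
                _add(lib, seq + bb, cb)
        if n_shift:
            m_rm = rng.binomial(n_shift, 0.5)
            _add(lib, seq[1:], m_rm)
            for b, cb in zip(DNA_BASES, rng.multinomial(n_shift - m_rm, [0.25] * 4)):
                _add(lib, b + seq, cb)
        if n_edit:
            templates = [
                (pos, alt)
                for pos in range(2, 9)
                for alt in DNA_BASES
                if alt != seq[pos - 1]
            ]
            for (pos, alt), cb in zip(
                templates, rng.multinomial(n_edit, [1 / 21] * 21)
            ):
                if cb:
                    edited = seq[: pos - 1] + alt + seq[pos:]
                    _add(lib, edited, cb)
                    manifest.append(
                        (library, names[i], pos, seq[pos - 1], alt, int(cb))
                    )

    if n_contam:
        n_polya, n_short, n_random = rng.multinomial(n_contam, [1 / 3, 1 / 3, 1 / 3])
        for length, cb in zip(*np.unique(rng.integers(18, 31, n_polya), return_counts=True)):
            _add(lib, "A" * int(length), int(cb))
        for _ in range(int(n_short)):
            _add(lib, _random_seq(rng, int(rng.integers(8, 16))), 1)
        for _ in range(int(n_random)):
            _add(lib, _random_seq(rng, int(rng.integers(18, 31))), 1)

    if config.error_rate > 0:
        lib = _apply_errors(lib, config.error_rate, rng)
    return lib, manifest, n_contam


def _apply_errors(
    lib: dict[str, int], rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Per-base substitution errors; a read with any error gets one substituted base.

    (At the low per-base rates simulated, multi-error reads are negligible; the
    per-read error probability 1-(1-rate)^L is exact.)
    """
    out: dict[str, int] = {}
    for seq, c in lib.items():
        length = len(seq)
        n_err = rng.binomial(c, 1.0 - (1.0 - rate) ** length)
        _add(out, seq, c - n_err)
        for _ in range(int(n_err)):
            pos = int(rng.integers(length))
            alt = str(rng.choice([b for b in DNA_BASES if b != seq[pos]]))
            _add(out, seq[:pos] + alt + seq[pos + 1 :], 1)
    return out


@dataclass
class SimulatedLibraries:
    """Collapsed simulated read libraries plus the planted-variant manifest."""

    lib_a: dict[str, int]
    lib_b: dict[str, int]
    manifest: pd.DataFrame
    contaminant_reads: dict[str, int]

    def tagset(self, library: str) -> TagSet:
        lib = {"a": self.lib_a, "b": self.lib_b}[library]
        return TagSet(counts=dict(lib), library_label=library)


def simulate_reads(
    catalog: Catalog,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedLibraries:
    """Draw both read libraries from the ground truth.

    Catalog-derived reads are multinomial in the true TPMs; each read independently
    stays canonical or becomes a 3' trim (1-2 nt, geometric), 3' addition (1-2 random
    nt), 5' shift (±1 nt) or seed edit (one random substitution at positions 2-8,
    from != to).  Contaminants are appended, per-base errors applied last.  The
    returned manifest records every realized seed-edit template with its planted read
    count (pre-error); contaminant totals update ``truth`` in place.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    libs = {}
    manifests = []
    contam = {}
    for library, depth, col in (
        ("a", config.depth_a, "tpm_a"),
        ("b", config.depth_b, "tpm_b"),
    ):
        lib, manifest, n_contam = _simulate_library(
            catalog, truth.table[col].to_numpy(), depth, config, rng, library
        )
        libs[library] = lib
        manifests.extend(manifest)
        contam[library] = n_contam
    manifest_df = pd.DataFrame(
        manifests, columns=["library", "mirna", "position", "from", "to", "count"]
    )
    truth.manifest = manifest_df
    truth.contaminant_reads = dict(contam)
    return SimulatedLibraries(
        lib_a=libs["a"],
        lib_b=libs["b"],
        manifest=manifest_df,
        contaminant_reads=contam,
    )


def write_fastq(lib: dict[str, int], path, read_prefix: str = "read") -> None:
    """Expand a collapsed library to FASTQ with constant Phred-40 qualities."""
    serial = 0
    with open(path, "w") as fh:
        for seq, count in lib.items():
            qual = "I" * len(seq)
            for _ in range(count):
                serial += 1
                fh.write(f"@{read_prefix}_{serial}\n{seq}\n+\n{qual}\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False, na_rep=".")


def write_manifest_tsv(truth: GroundTruth, path) -> None:
    truth.manifest.to_csv(path, sep="\t", index=False, na_rep=".")


def simulate_all(
    config: SimulationConfig,
) -> tuple[Catalog, GroundTruth, SimulatedLibraries]:
    """Catalog -> abundances -> reads under one config-derived RNG stream."""
    rng = np.random.default_rng(config.seed)
    catalog = simulate_catalog(config.n_mirnas, config.length_range, rng)
    truth = simulate_abundances(catalog, config, rng)
    libs = simulate_reads(catalog, truth, config, rng)
    return catalog, truth, libs
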