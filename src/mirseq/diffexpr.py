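"""Differential miRNA expression between two pooled count libraries.

The design has no replicates: each condition is one pooled sequencing library, so
dispersion-based tools (negative-binomial GLMs) do not apply.  Instead each miRNA is
tested with the exact conditional statistic for two count libraries (the
Audic-Claverie family): given a miRNA observed ``y`` times in a library of ``N2``
clean reads, the probability of observing it ``x`` times in a library of ``N1`` reads
under equal underlying expression is

    p(x | y) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

Algebraically this is a negative-binomial mass:  p(x|y) = NB(y; x+1, N1/(N1+N2)), and
equivalently (N1/N2) * NB(x; y+1, N2/(N1+N2)), which is how tail sums are computed
here (stable, no explicit series).  Two-sided p-values double the smaller tail and cap
at 1; the literal point mass is retained as ``mode="point"`` for users who want the
printed formula untouched.

``x`` and ``y`` are raw counts — the factorials demand integers — while fold changes
are computed on TPM.  Filtering (TPM floor, optional confidence score), BH-FDR and the
up/down calls follow the conventional two-library workflow: adjusted P < 0.05 and
|log2 fold change| > 1 by default.

The module exposes both a functional surface (``ac_pvalue``, ``bh_adjust``,
``call_dems``) and a model-object surface (:class:`DifferentialExpression` whose
``fit`` returns :class:`DifferentialExpressionResults`).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionProfile

# Fold-change sentinels for miRNAs detected in only one library
EXCLUSIVE_LIB1 = "exclusive_lib1"
EXCLUSIVE_LIB2 = "exclusive_lib2"
UNDEFINED = "undefined"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"
STATUS_FILTERED_FLOOR = "filtered_floor"
STATUS_FILTERED_CONFIDENCE = "filtered_confidence"

DEM_COLUMNS = [
    "mirna",
    "count_1",
    "count_2",
    "tpm_1",
    "tpm_2",
    "log2fc",
    "p_raw",
    "p_adj",
    "status",
]


def _validate_counts(x, y, n1: float, n2: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive (N1={n1}, N2={n2})")
    for arr, label in ((x, "x"), (y, "y")):
        if np.any(arr < 0):
            raise ValueError(f"{label} contains negative counts")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{label} contains non-integer counts")
    return x.astype(np.int64), y.astype(np.int64)


def ac_point_prob(x: int, y: int, n1: float, n2: float) -> float:
    """Point mass p(x|y) of the exact conditional test, in log-gamma space.

    Finite and in (0, 1] for counts up to ~1e7.
    """
    xa, ya = _validate_counts(x, y, n1, n2)
    ratio = n2 / n1
    logp = (
        ya * np.log(ratio)
        + gammaln(xa + ya + 1)
        - gammaln(xa + 1)
        - gammaln(ya + 1)
        - (xa + ya + 1) * np.log1p(ratio)
    )
    out = np.exp(logp)
    return float(out) if np.ndim(x) == 0 and np.ndim(y) == 0 else out


def ac_point_prob_oracle(x: int, y: int, n1, n2) -> float:
    """Exact-rational evaluation of p(x|y); independent check for the log-space path.

    Supported for x + y <= 200 (factorials carried exactly).
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("x and y must be non-negative integers")
    x, y = int(x), int(y)
    if x + y > 200:
        raise ValueError("oracle supports x + y <= 200 only")
    q = Fraction(n2) / Fraction(n1)
    p = q**y * comb(x + y, x) * (1 + q) ** -(x + y + 1)
    return float(p)


def _ac_tails(x: np.ndarray, y: np.ndarray, n1: float, n2: float):
    """Lower tail P(X <= x | y) and upper tail 1 - P(X < x | y).

    Uses p(x|y) = (N1/N2) * NB(x; y+1, N2/(N1+N2)); the upper tail is defined as the
    complement of the strict lower tail, clipped to [0, 1].
    """
    ratio = n1 / n2
    b = n2 / (n1 + n2)
    lower = ratio * nbinom.cdf(x, y + 1, b)
    lower_strict = np.where(x > 0, ratio * nbinom.cdf(x - 1, y + 1, b), 0.0)
    upper = np.clip(1.0 - lower_strict, 0.0, 1.0)
    return lower, upper


def ac_pvalue(x, y, n1: float, n2: float, mode: str = "two_sided"):
    """P-value of the exact conditional test.

    ``two_sided`` doubles the smaller of the two tails (point included in each) and
    caps at 1 — the conventional exact-test construction.  ``point`` returns the
    literal point mass p(x|y).  Accepts scalars or arrays.
    """
    xa, ya = _validate_counts(x, y, n1, n2)
    if mode == "point":
        p = ac_point_prob(xa, ya, n1, n2)
    elif mode == "two_sided":
        lower, upper = _ac_tails(xa, ya, n1, n2)
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    return float(p) if np.ndim(x) == 0 and np.ndim(y) == 0 else np.asarray(p)


def log2_fold_change(tpm1: float, tpm2: float, pseudocount: float = 0.0):
    """log2((tpm2 + pseudocount) / (tpm1 + pseudocount)), condition 2 over 1.

    With ``pseudocount == 0`` a zero on one side yields the matching exclusive
    sentinel string (the miRNA is detected in only one library); zero on both sides
    yields the undefined sentinel.
    """
    if tpm1 < 0 or tpm2 < 0:
        raise ValueError("TPM values must be non-negative")
    a, b = tpm1 + pseudocount, tpm2 + pseudocount
    if a == 0 and b == 0:
        return UNDEFINED
    if a == 0:
        return EXCLUSIVE_LIB2
    if b == 0:
        return EXCLUSIVE_LIB1
    return float(np.log2(b / a))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def call_dems(
    paired: pd.DataFrame,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
    tpm_floor: float = 1.0,
    confidence_floor: float = 0.95,
    pvalue_mode: str = "two_sided",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Run the full DEM-calling procedure on a paired two-library count table.

    ``paired`` needs columns ``mirna, count_1, count_2, tpm_1, tpm_2`` and may carry
    ``confidence`` (defaults to 1.0; catalog miRNAs are never confidence-filtered).

    Procedure: (1) drop miRNAs with TPM below ``tpm_floor`` in *both* libraries;
    (2) drop miRNAs with confidence below ``confidence_floor``; (3) compute log2 fold
    change on TPM and the exact conditional p-value on raw counts; (4) BH-adjust over
    the surviving tests; (5) call up/down at adjusted P < alpha and |log2FC| >
    ``fc_threshold`` (strict inequalities).  Library-exclusive miRNAs that pass the
    floor are decided on adjusted P alone, with direction from the nonzero side;
    non-significant exclusives are reported with the exclusive status.
    """
    required = {"mirna", "count_1", "count_2", "tpm_1", "tpm_2"}
    missing = required - set(paired.columns)
    if missing:
        raise ValueError(f"paired table is missing columns: {sorted(missing)}")
    df = paired.reset_index(drop=True)
    x, y = _validate_counts(df["count_1"].to_numpy(), df["count_2"].to_numpy(), n1, n2)
    if np.any(x > n1) or np.any(y > n2):
        raise ValueError("a count exceeds its library total; inconsistent N1/N2")
    confidence = (
        df["confidence"].to_numpy(dtype=float)
        if "confidence" in df.columns
        else np.ones(len(df))
    )
    tpm1 = df["tpm_1"].to_numpy(dtype=float)
    tpm2 = df["tpm_2"].to_numpy(dtype=float)

    status = np.full(len(df), STATUS_NS, dtype=object)
    log2fc = np.full(len(df), np.nan)
    p_raw = np.full(len(df), np.nan)
    p_adj = np.full(len(df), np.nan)

    floored = (tpm1 < tpm_floor) & (tpm2 < tpm_floor)
    status[floored] = STATUS_FILTERED_FLOOR
    low_conf = ~floored & (confidence < confidence_floor)
    status[low_conf] = STATUS_FILTERED_CONFIDENCE
    tested = ~(floored | low_conf)

    idx = np.flatnonzero(tested)
    if idx.size:
        p_raw[idx] = ac_pvalue(x[idx], y[idx], n1, n2, mode=pvalue_mode)
        p_adj[idx] = bh_adjust(p_raw[idx])
        for i in idx:
            fc = log2_fold_change(tpm1[i], tpm2[i], pseudocount)
            sig = p_adj[i] < alpha
            if isinstance(fc, str):
                if fc == EXCLUSIVE_LIB2:
                    log2fc[i] = np.inf
                    status[i] = STATUS_UP if sig else EXCLUSIVE_LIB2
                elif fc == EXCLUSIVE_LIB1:
                    log2fc[i] = -np.inf
                    status[i] = STATUS_DOWN if sig else EXCLUSIVE_LIB1
                else:  # undefined: zero in both (only reachable at tpm_floor == 0)
                    status[i] = STATUS_NS
            else:
                log2fc[i] = fc
                if sig and fc > fc_threshold:
                    status[i] = STATUS_UP
                elif sig and fc < -fc_threshold:
                    status[i] = STATUS_DOWN

    return pd.DataFrame(
        {
            "mirna": df["mirna"],
            "count_1": x,
            "count_2": y,
            "tpm_1": tpm1,
            "tpm_2": tpm2,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "status": status,
        }
    )


@dataclass
class DemRecord:
    """One miRNA's differential-expression result."""

    mirna: str
    log2fc: float
    p_raw: float
    p_adj: float
    status: str


class DifferentialExpression:
    """Exact conditional differential-expression model for two pooled libraries.

    Parameters
    ----------
    data :
        Paired table with columns ``mirna, count_1, count_2, tpm_1, tpm_2`` and an
        optional ``confidence`` column.
    n1, n2 :
        Total clean reads of libraries 1 and 2 (the TPM denominators); the test
        conditions on them.
    """

    def __init__(self, data: pd.DataFrame, n1: int, n2: int):
        if n1 < 1 or n2 < 1:
            raise ValueError("library totals must be >= 1")
        self.data = data.reset_index(drop=True)
        self.n1 = int(n1)
        self.n2 = int(n2)

    @classmethod
    def from_profiles(
        cls,
        profile_1: ExpressionProfile,
        profile_2: ExpressionProfile,
        confidence: Optional[dict[str, float]] = None,
    ) -> "DifferentialExpression":
        """Build the paired table from two per-library expression profiles."""
        names = list(profile_1.counts)
        extra = [n for n in profile_2.counts if n not in profile_1.counts]
        names += extra
        rows = {
            "mirna": names,
            "count_1": [profile_1.counts.get(n, 0) for n in names],
            "count_2": [profile_2.counts.get(n, 0) for n in names],
            "tpm_1": [profile_1.tpm.get(n, 0.0) for n in names],
            "tpm_2": [profile_2.tpm.get(n, 0.0) for n in names],
        }
        if confidence is not None:
            rows["confidence"] = [confidence.get(n, 1.0) for n in names]
        return cls(
            pd.DataFrame(rows),
            n1=profile_1.library_total_clean_reads,
            n2=profile_2.library_total_clean_reads,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n1: Optional[int] = None,
        n2: Optional[int] = None,
    ) -> "DifferentialExpression":
        """Build from a combined table; N totals may come from ``n_1``/``n_2`` columns,
        which must then be constant across rows."""
        df = df.copy()
        for col, val in (("n_1", n1), ("n_2", n2)):
            if val is None:
                if col not in df.columns:
                    raise ValueError(f"{col} column or explicit total required")
                uniq = df[col].unique()
                if len(uniq) != 1:
                    raise ValueError(f"{col} must be constant across rows, got {uniq}")
                val = int(uniq[0])
            if col == "n_1":
                n1 = int(val)
            else:
                n2 = int(val)
        return cls(df.drop(columns=[c for c in ("n_1", "n_2") if c in df]), n1, n2)

    def fit(
        self,
        alpha: float = 0.05,
        fc_threshold: float = 1.0,
        tpm_floor: float = 1.0,
        confidence_floor: float = 0.95,
        pvalue_mode: str = "two_sided",
        pseudocount: float = 0.0,
    ) -> "DifferentialExpressionResults":
        table = call_dems(
            self.data,
            self.n1,
            self.n2,
            alpha=alpha,
            fc_threshold=fc_threshold,
            tpm_floor=tpm_floor,
            confidence_floor=confidence_floor,
            pvalue_mode=pvalue_mode,
            pseudocount=pseudocount,
        )
        params = dict(
            alpha=alpha,
            fc_threshold=fc_threshold,
            tpm_floor=tpm_floor,
            confidence_floor=confidence_floor,
            pvalue_mode=pvalue_mode,
            pseudocount=pseudocount,
            n1=self.n1,
            n2=self.n2,
        )
        return DifferentialExpressionResults(self, table, params)


class DifferentialExpressionResults:
    """Fitted DEM calls: the per-miRNA table plus call counts and a text summary."""

    def __init__(self, model: DifferentialExpression, table: pd.DataFrame, params: dict):
        self.model = model
        self.table = table
        self.params = params

    @property
    def n_up(self) -> int:
        return int((self.table["status"] == STATUS_UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["status"] == STATUS_DOWN).sum())

    @property
    def n_tested(self) -> int:
        return int(self.table["p_raw"].notna().sum())

    def records(self) -> list[DemRecord]:
        return [
            DemRecord(r.mirna, r.log2fc, r.p_raw, r.p_adj, r.status)
            for r in self.table.itertuples(index=False)
        ]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["status"].isin([STATUS_UP, STATUS_DOWN])]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=".")

    def summary(self) -> str:
        p = self.params
        counts = self.table["status"].value_counts()
        lines = [
            "Differential miRNA expression (exact conditional two-library test)",
            "=" * 68,
            f"Library totals          N1 = {p['n1']:,}   N2 = {p['n2']:,}",
            f"miRNAs in table         {len(self.table)}",
            f"Tested (post-filter)    {self.n_tested}",
            f"Thresholds              adj. P < {p['alpha']}, |log2FC| > {p['fc_threshold']}",
            f"TPM floor / confidence  {p['tpm_floor']} / {p['confidence_floor']}",
            f"P-value mode            {p['pvalue_mode']}",
            "-" * 68,
        ]
        for status in (
            STATUS_UP,
            STATUS_DOWN,
            STATUS_NS,
            EXCLUSIVE_LIB1,
            EXCLUSIVE_LIB2,
            STATUS_FILTERED_FLOOR,
            STATUS_FILTERED_CONFIDENCE,
        ):
            lines.append(f"{status:<24}{int(counts.get(status, 0))}")
        return "\n".join(lines)
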