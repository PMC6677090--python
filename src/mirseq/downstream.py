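"""Term enrichment and qPCR relative-expression validation.

Enrichment is a classical over-representation test: for a query gene set of size n
drawn from a universe of M annotated genes, a term annotating K genes and overlapping
the query in k genes has p = P(X >= k) under the hypergeometric null, BH-adjusted
across terms (Q).  The term map is a plain TSV (term<TAB>gene); no ontology files or
DAG propagation — term definitions are the caller's responsibility.

The 2^-ddCt computation mirrors standard stem-loop qRT-PCR validation: Ct of the
target is referenced to an internal control (e.g. U6 snRNA) per sample, group-mean
delta-Ct values are differenced between treatment and control, and the result is
expressed as a fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


@dataclass
class TermMap:
    """term -> gene set, over an explicit annotation universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("annotation universe must be non-empty")
        for term, genes in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_tsv(cls, path, universe: set[str] | None = None) -> "TermMap":
        """Long-format TSV ``term<TAB>gene``; universe defaults to all mapped genes."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["term", "gene"], dtype=str,
            comment="#",
        )
        terms: dict[str, set[str]] = {}
        for term, gene in zip(df["term"], df["gene"]):
            terms.setdefault(term, set()).add(gene)
        if universe is None:
            universe = set(df["gene"])
        return cls(terms=terms, universe=universe)


def hypergeom_enrich(query: set[str], term_map: TermMap) -> pd.DataFrame:
    """Over-representation p and BH-adjusted q per term.

    Query genes outside the universe are dropped (a warning reports how many).
    Terms with zero overlap are reported with p = 1.  Columns: term, k (overlap),
    K (term size), n (query size), M (universe size), p, q.
    """
    universe = term_map.universe
    inside = query & universe
    dropped = len(query) - len(inside)
    if dropped:
        warnings.warn(
            f"{dropped} query gene(s) outside the annotation universe were dropped"
        )
    m_total = len(universe)
    n = len(inside)
    rows = []
    for term, genes in term_map.terms.items():
        big_k = len(genes)
        k = len(inside & genes)
        # upper tail P(X >= k); k = 0 is certain
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, m_total, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "M": m_total, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "M", "p"])
    df["q"] = bh_adjust(df["p"].tolist()) if len(df) else []
    df.attrs["dropped_query_genes"] = dropped
    return df


GROUP_TREATMENT = "treatment"
GROUP_CONTROL = "control"


@dataclass
class DdctResult:
    """2^-ddCt fold change with the per-sample delta-Ct values behind it."""

    fold_change: float
    ddct: float
    dct_treatment: "pd.Series"
    dct_control: "pd.Series"

    @property
    def per_sample_fold(self) -> pd.Series:
        """Per-treatment-sample 2^-(dCt - mean control dCt)."""
        return 2.0 ** -(self.dct_treatment - self.dct_control.mean())


def _dct(table: pd.DataFrame, group: str, reference_gene: str, target_gene: str) -> pd.Series:
    sub = table[table["group"] == group]
    out = {}
    for sample, block in sub.groupby("sample"):
        ct = dict(zip(block["gene"], block["ct"]))
        for gene in (reference_gene, target_gene):
            if gene not in ct:
                raise ValueError(f"sample {sample!r} ({group}) lacks a Ct for {gene!r}")
        out[sample] = float(ct[target_gene]) - float(ct[reference_gene])
    if not out:
        raise ValueError(f"no samples in group {group!r}")
    return pd.Series(out).sort_index()


def ddct(
    table: pd.DataFrame, reference_gene: str, target_gene: str
) -> DdctResult:
    """Relative expression of ``target_gene`` vs ``reference_gene``, 2^-ddCt.

    ``table`` holds rows (sample, group in {treatment, control}, gene, ct).
    delta-Ct = Ct(target) - Ct(reference) per sample; delta-delta-Ct is the
    difference of group means (treatment minus control); the fold change is
    2^-ddCt, so one cycle earlier in treatment doubles the call.
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    dct_t = _dct(table, GROUP_TREATMENT, reference_gene, target_gene)
    dct_c = _dct(table, GROUP_CONTROL, reference_gene, target_gene)
    ddct_value = float(dct_t.mean() - dct_c.mean())
    return DdctResult(
        fold_change=float(2.0**-ddct_value),
        ddct=ddct_value,
        dct_treatment=dct_t,
        dct_control=dct_c,
    )


def read_ct_tsv(path) -> pd.DataFrame:
    """Ct TSV with columns sample, group, gene, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "gene": str})
    df["ct"] = df["ct"].astype(float)
    return df
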