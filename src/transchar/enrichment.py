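"""GO-term enrichment by one-sided Fisher exact test with BH FDR control.

Two annotated ORF sets (a target and a background, or two species'
annotated transcriptomes) are compared term by term on 2x2 tables of
"has term / lacks term" counts.  Over-representation in the target is the
hypothesis of interest — under-representation is deliberately not tested —
so the default is the one-sided (greater) Fisher exact test, i.e. the
hypergeometric upper tail.  Benjamini–Hochberg step-up adjustment controls
the false discovery rate across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "fisher_exact_greater",
    "bh_adjust",
    "compare_term_proportions",
    "ssr_orf_enrichment",
    "read_term_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: target with/without the term, background with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_exact_greater(t: ContingencyTable) -> float:
    """One-sided Fisher exact p-value P(X >= a) for over-representation.

    X is hypergeometric with the table's margins fixed.
    """
    _, p = stats.fisher_exact(
        [[t.a, t.b], [t.c, t.d]], alternative="greater"
    )
    return float(p)


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (sum of outcomes no more probable)."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, order-preserving.

    adjusted_(i) = min_{j >= i} m * p_(j) / j, capped at 1, mapped back to
    the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _dedup(table: Iterable[tuple[str, str]], name: str) -> pd.DataFrame:
    df = pd.DataFrame(list(table), columns=["orf_id", "term_id"])
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        warnings.warn(
            f"{name}: removed {n0 - len(df)} duplicate (orf, term) pairs",
            stacklevel=3,
        )
    return df


def compare_term_proportions(
    annot_a: Iterable[tuple[str, str]],
    annot_b: Iterable[tuple[str, str]],
    alpha: float = 0.05,
    sided: str = "greater",
) -> pd.DataFrame:
    """Per-term enrichment of set A over set B.

    Each input is an (orf_id, term_id) table; the ORF universe of each set
    is its distinct ORF ids, and term counts are de-duplicated per ORF.
    Returns one row per term in the union with the 2x2 counts, the Fisher
    p-value, the BH-adjusted q and the enrichment flag at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sided not in ("greater", "two-sided"):
        raise ValueError(f"sided must be 'greater' or 'two-sided', got {sided!r}")
    da = _dedup(annot_a, "annot_a")
    db = _dedup(annot_b, "annot_b")
    if da.empty or db.empty:
        raise ValueError("both annotation tables must be non-empty")
    n_a = da["orf_id"].nunique()
    n_b = db["orf_id"].nunique()
    counts_a = da.groupby("term_id")["orf_id"].nunique()
    counts_b = db.groupby("term_id")["orf_id"].nunique()
    terms = sorted(set(counts_a.index) | set(counts_b.index))
    test = fisher_exact_greater if sided == "greater" else fisher_exact_two_sided
    rows = []
    for term in terms:
        a = int(counts_a.get(term, 0))
        c = int(counts_b.get(term, 0))
        tab = ContingencyTable(a=a, b=n_a - a, c=c, d=n_b - c)
        rows.append(
            {
                "term_id": term,
                "a": tab.a,
                "b": tab.b,
                "c": tab.c,
                "d": tab.d,
                "p": test(tab),
            }
        )
    res = pd.DataFrame(
        rows, columns=["term_id", "a", "b", "c", "d", "p"]
    )
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["enriched"] = res["q"] <= alpha
    else:
        res["q"] = []
        res["enriched"] = []
    return res


def ssr_orf_enrichment(
    annot: Iterable[tuple[str, str]],
    ssr_orf_ids: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    sided: str = "greater",
) -> dict[str, pd.DataFrame]:
    """Enrichment of SSR-bearing annotated ORFs per motif class.

    ``ssr_orf_ids`` maps a motif-class label (e.g. ``"tri"``) to the ORF
    ids carrying that repeat class.  For each class the target set is the
    annotated ORFs among those ids and the background is the remaining
    annotated ORFs; non-annotated ORFs are excluded from both sides.
    """
    da = _dedup(annot, "annot")
    if da.empty:
        raise ValueError("annotation table must be non-empty")
    annotated = set(da["orf_id"])
    results: dict[str, pd.DataFrame] = {}
    for label, ids in ssr_orf_ids.items():
        target = annotated & set(ids)
        background = annotated - target
        if not target or not background:
            warnings.warn(
                f"motif class {label!r}: empty target or background after "
                "restricting to annotated ORFs; no tests performed",
                stacklevel=2,
            )
            results[label] = pd.DataFrame(
                columns=["term_id", "a", "b", "c", "d", "p", "q", "enriched"]
            )
            continue
        in_t = da["orf_id"].isin(target)
        results[label] = compare_term_proportions(
            da[in_t].itertuples(index=False, name=None),
            da[~in_t].itertuples(index=False, name=None),
            alpha=alpha,
            sided=sided,
        )
    return results


def read_term_table(path) -> list[tuple[str, str]]:
    """Read a two-column (orf_id, term_id) TSV, with or without header."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["orf_id", "term_id"]
    if list(df.iloc[0]) == ["orf_id", "term_id"]:
        df = df.iloc[1:]
    return list(df.itertuples(index=False, name=None))
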