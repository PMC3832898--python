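"""Statistical layer of the branch-site positive-selection screen.

The upstream heavy lifting (ortholog clustering, codon alignment,
maximum-likelihood fitting of the branch-site null and alternative
models) is consumed as input; this module implements the decision layer:

* restriction to single-copy core gene clusters (exactly one member per
  species, no paralogs);
* alignment-column filtering on per-column posterior probabilities, with
  whole-alignment discard when more than half the sites are removed;
* the likelihood-ratio test, with the statistic 2*(lnL_alt - lnL_null)
  referred to a chi-square distribution with one degree of freedom (a
  50:50 point-mass/chi-square mixture is available as an option);
* Benjamini–Hochberg FDR selection of significant genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

__all__ = [
    "ClusterMembership",
    "ColumnFilterOutcome",
    "single_copy_core",
    "filter_columns",
    "branch_site_lrt",
    "evaluate_lrt_table",
    "fdr_select",
]

_LNL_TOL = 1e-8


@dataclass(frozen=True)
class ClusterMembership:
    """A homologous-gene cluster: (species_id, gene_id) members."""

    cluster_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")


@dataclass(frozen=True)
class ColumnFilterOutcome:
    kept_columns: tuple[int, ...]
    fraction_removed: float
    discarded: bool


def single_copy_core(
    clusters: Iterable[ClusterMembership], species: Iterable[str]
) -> list[str]:
    """Ids of clusters with exactly one member per species and none extra.

    Clusters containing paralogs (two genes from one species) or missing a
    species are excluded.
    """
    wanted = set(species)
    kept = []
    for cl in clusters:
        sp = [s for s, _ in cl.members]
        if set(sp) == wanted and len(sp) == len(wanted):
            kept.append(cl.cluster_id)
    return kept


def filter_columns(
    posteriors: Sequence[float],
    threshold: float = 0.6,
    max_removed: float = 0.5,
) -> ColumnFilterOutcome:
    """Drop alignment columns with posterior probability below ``threshold``.

    The alignment is discarded when *strictly* more than ``max_removed`` of
    its columns are removed; removing exactly half keeps it.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.size == 0:
        raise ValueError("posterior vector must be non-empty")
    if np.any(post < 0) or np.any(post > 1):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    keep = post >= threshold
    frac_removed = float(1.0 - keep.mean())
    return ColumnFilterOutcome(
        kept_columns=tuple(int(i) for i in np.flatnonzero(keep)),
        fraction_removed=frac_removed,
        discarded=frac_removed > max_removed,
    )


def branch_site_lrt(
    lnl_null: float, lnl_alt: float, mixture: bool = False
) -> tuple[float, float]:
    """(LRT statistic, p-value) for one gene.

    stat = max(0, 2*(lnL_alt - lnL_null)); p is the chi-square(df=1) upper
    tail, or with ``mixture`` the 50:50 mixture of a point mass at 0 and
    chi-square(1) sometimes used for boundary null hypotheses.  A negative
    statistic beyond numerical tolerance is an optimizer artifact and is
    floored at 0 with a warning.
    """
    if not (np.isfinite(lnl_null) and np.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    raw = 2.0 * (lnl_alt - lnl_null)
    if raw < -_LNL_TOL:
        warnings.warn(
            f"alternative lnL {lnl_alt} below null lnL {lnl_null}; "
            "statistic floored at 0 (optimizer artifact)",
            stacklevel=2,
        )
    stat = max(0.0, raw)
    tail = float(stats.chi2.sf(stat, df=1))
    if mixture:
        p = 0.5 * tail if stat > 0 else 1.0
    else:
        p = tail
    return stat, p


def evaluate_lrt_table(
    lnl_pairs: Iterable[tuple[str, float, float]],
    alpha: float = 0.05,
    mixture: bool = False,
) -> pd.DataFrame:
    """LRT statistics, p, BH q and significance flags for a gene table.

    ``lnl_pairs`` yields (gene_id, lnL_null, lnL_alt).
    """
    rows = []
    for gene_id, lnl0, lnl1 in lnl_pairs:
        stat, p = branch_site_lrt(lnl0, lnl1, mixture=mixture)
        rows.append(
            {
                "gene_id": gene_id,
                "lnl_null": float(lnl0),
                "lnl_alt": float(lnl1),
                "stat": stat,
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "lnl_null", "lnl_alt", "stat", "p"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] <= alpha
    else:
        df["q"] = []
        df["significant"] = []
    return df


def fdr_select(
    results: Iterable[tuple[str, float]], alpha: float = 0.05
) -> list[str]:
    """Gene ids passing BH step-up selection at level ``alpha``.

    ``results`` yields (gene_id, p).  Selection is invariant to input
    order; returned ids are in input order.
    """
    items = list(results)
    if not items:
        raise ValueError("fdr_select requires at least one result")
    q = bh_adjust([p for _, p in items])
    return [gene for (gene, _), qi in zip(items, q) if qi <= alpha]
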