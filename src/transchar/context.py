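"""Genomic-context classification of SSRs and amino-acid homopolymers.

Every microsatellite on a transcript with an ORF call falls in exactly one
of five contexts relative to the reading orientation: inside the coding
span, in the 5' or 3' UTR, or straddling the start (5') or stop (3')
boundary.  Transcripts without a qualifying ORF are putative non-coding
transcripts and their SSRs are labelled NONCODING.

The stop codon's three bases belong to neither the coding span nor, for
containment purposes, do they demote an SSR: a repeat touching only the
stop codon and the 3'UTR is a UTR3 locus.  A repeat long enough to cross
both boundaries of a very short ORF takes the 5' label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orfs import OrfCall
from .ssr import SsrLocus

__all__ = [
    "Region",
    "HomopolymerRun",
    "classify_ssr",
    "region_summary",
    "find_homopolymers",
    "homopolymer_composition",
]


class Region(str, enum.Enum):
    ORF = "ORF"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    STRADDLE5 = "STRADDLE5"
    STRADDLE3 = "STRADDLE3"
    NONCODING = "NONCODING"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


def classify_ssr(
    ssr: SsrLocus,
    orf: OrfCall | None,
    transcript_length: int | None = None,
) -> Region:
    """Assign a region label to one SSR given the transcript's ORF call.

    Reading-orientation aware: for a reverse-strand ORF the 5' boundary is
    the coding span's high coordinate.  ``transcript_length``, when given,
    is used to bounds-check the SSR interval.
    """
    if transcript_length is not None and not (
        0 <= ssr.start < ssr.end <= transcript_length
    ):
        raise ValueError(
            f"SSR interval [{ssr.start},{ssr.end}) outside transcript "
            f"of length {transcript_length}"
        )
    if orf is None:
        return Region.NONCODING
    if orf.transcript_id != ssr.transcript_id:
        raise ValueError(
            f"SSR transcript {ssr.transcript_id!r} does not match "
            f"ORF transcript {orf.transcript_id!r}"
        )
    s, e = ssr.start, ssr.end
    overlaps_coding = s < orf.end and e > orf.start
    if orf.strand == "+":
        if not overlaps_coding:
            return Region.UTR5 if e <= orf.start else Region.UTR3
        if s >= orf.start and e <= orf.end:
            return Region.ORF
        # 5' boundary takes precedence for double straddles
        return Region.STRADDLE5 if s < orf.start else Region.STRADDLE3
    else:
        if not overlaps_coding:
            return Region.UTR5 if s >= orf.end else Region.UTR3
        if s >= orf.start and e <= orf.end:
            return Region.ORF
        return Region.STRADDLE5 if e > orf.end else Region.STRADDLE3


_REGION_ORDER = [r.value for r in Region]


def region_summary(
    labeled: Sequence[tuple[SsrLocus, Region]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(overall region table, per-region period-class table).

    The first table carries counts and proportions per region label; the
    second the period-class composition within each region (proportions
    within region).  Counts are retained alongside proportions.
    """
    rows = [
        {"region": reg.value, "period": ssr.period} for ssr, reg in labeled
    ]
    df = pd.DataFrame(rows, columns=["region", "period"])
    total = len(df)
    reg = df.groupby("region").size().to_frame("count")
    reg = reg.reindex([r for r in _REGION_ORDER if r in reg.index])
    reg["proportion"] = reg["count"] / total if total else 0.0
    by = (
        df.groupby(["region", "period"]).size().to_frame("count").reset_index()
    )
    if total:
        by["proportion"] = by.groupby("region")["count"].transform(
            lambda c: c / c.sum()
        )
    else:
        by["proportion"] = []
    return reg, by


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one amino-acid residue within an ORF translation."""

    orf_id: str
    residue: str
    length: int
    start: int


def find_homopolymers(
    aa_seq: str, min_len: int = 5, orf_id: str = ""
) -> list[HomopolymerRun]:
    """Maximal single-residue runs of length >= ``min_len``; X excluded."""
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    runs: list[HomopolymerRun] = []
    i, n = 0, len(aa_seq)
    while i < n:
        j = i + 1
        while j < n and aa_seq[j] == aa_seq[i]:
            j += 1
        if j - i >= min_len and aa_seq[i] not in ("X", "*"):
            runs.append(
                HomopolymerRun(
                    orf_id=orf_id, residue=aa_seq[i], length=j - i, start=i
                )
            )
        i = j
    return runs


def homopolymer_composition(
    orf_translations: Mapping[str, str] | Iterable[tuple[str, str]],
    min_len: int = 5,
) -> pd.DataFrame:
    """Per-residue homopolymer-run composition of an ORF subset.

    Returns a table indexed by residue with the count of runs and each
    residue's share of all runs in the subset.  A subset with no runs
    yields a defined empty table; an empty subset is an error.
    """
    items = (
        orf_translations.items()
        if isinstance(orf_translations, Mapping)
        else list(orf_translations)
    )
    items = list(items)
    if not items:
        raise ValueError("homopolymer_composition requires a non-empty ORF subset")
    runs: list[HomopolymerRun] = []
    for orf_id, aa in items:
        runs.extend(find_homopolymers(aa, min_len=min_len, orf_id=orf_id))
    if not runs:
        return pd.DataFrame(columns=["count", "proportion"]).rename_axis("residue")
    df = pd.DataFrame({"residue": [r.residue for r in runs]})
    out = df.groupby("residue").size().to_frame("count")
    out["proportion"] = out["count"] / len(runs)
    return out.sort_values("count", ascending=False)
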