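"""Perfect microsatellite (SSR) detection and motif canonicalization.

A microsatellite here is a perfect tandem repeat of a primitive 2-4 bp
motif with at least five complete units — no mismatches, no interruptions,
and ``N`` never matches inside a run.  Each maximal run is attributed to
its smallest period only, so (AT)6 is a dinucleotide locus, never a
tetranucleotide one.  Within a period class, runs are emitted left to
right and never overlap: a maximal run consumes its interval, including a
trailing partial unit, and the scan resumes past its end.

Motif classes are canonicalized under cyclic rotation and reverse
complementation (e.g. TG, GT, CA and AC all belong to class AC), which is
the convention used when tallying motif frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

from .orfs import Transcript

__all__ = [
    "SsrLocus",
    "is_primitive",
    "canonical_motif",
    "scan_ssrs",
    "summarize_catalog",
    "CatalogSummary",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SsrLocus:
    """One perfect tandem repeat locus.

    ``start``/``end`` delimit the maximal perfect run (0-based half-open),
    including any trailing partial unit; ``n_units`` counts complete units
    only.  ``motif`` is the unit as it first appears in the run; the
    ``canonical_motif`` is the class representative under rotation and
    reverse complement.
    """

    transcript_id: str
    start: int
    end: int
    period: int
    motif: str
    canonical_motif: str
    n_units: int

    def __post_init__(self) -> None:
        if self.period != len(self.motif):
            raise ValueError("period must equal motif length")
        run = self.end - self.start
        if not (self.period * self.n_units <= run < self.period * (self.n_units + 1)):
            raise ValueError("interval inconsistent with unit count")


def is_primitive(motif: str) -> bool:
    """True iff no proper divisor period reproduces ``motif``.

    ATAT has period 2 and is not primitive; AC and AAG are primitive.
    """
    if not 1 <= len(motif) <= 4:
        raise ValueError(f"motif length must be 1-4, got {motif!r}")
    if set(motif) - _ACGT:
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of ``motif`` or its reverse
    complement — the motif-class representative."""
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = reverse_complement(motif)
    n = len(motif)
    candidates = [motif[i:] + motif[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


def scan_ssrs(
    t: Transcript,
    periods: Sequence[int] = (2, 3, 4),
    min_units: int = 5,
) -> list[SsrLocus]:
    """All perfect tandem-repeat loci on ``t``, sorted by start then period.

    For each period independently, the scan walks left to right; a maximal
    perfect run (chain of positions where ``seq[i] == seq[i+p]`` over
    unambiguous bases) with a primitive motif and at least ``min_units``
    complete units is reported once, and the scan resumes after the run so
    same-period loci never overlap.  ``N`` terminates any run.
    """
    seq = t.seq
    L = len(seq)
    loci: list[SsrLocus] = []
    for p in sorted(set(periods)):
        if p < 1:
            raise ValueError(f"period must be positive, got {p}")
        pos = 0
        limit = L - p
        while pos < limit:
            c = seq[pos]
            if c != "N" and c == seq[pos + p]:
                b = pos
                while b < limit and seq[b] != "N" and seq[b] == seq[b + p]:
                    b += 1
                run_start, run_end = pos, b + p
                n_units = (run_end - run_start) // p
                motif = seq[run_start : run_start + p]
                if n_units >= min_units and "N" not in motif and is_primitive(motif):
                    loci.append(
                        SsrLocus(
                            transcript_id=t.id,
                            start=run_start,
                            end=run_end,
                            period=p,
                            motif=motif,
                            canonical_motif=canonical_motif(motif),
                            n_units=n_units,
                        )
                    )
                    pos = run_end
                else:
                    pos += 1
            else:
                pos += 1
    loci.sort(key=lambda x: (x.start, x.period))
    return loci


@dataclass(frozen=True)
class CatalogSummary:
    """Aggregate view of an SSR catalog.

    ``period_table``: per period class — count, proportion, max and mean
    complete-unit counts.  ``motif_table``: per canonical motif — count.
    """

    period_table: pd.DataFrame
    motif_table: pd.DataFrame
    total: int


def summarize_catalog(
    loci: Iterable[SsrLocus], round_means: int | None = None
) -> CatalogSummary:
    """Summarize an SSR catalog by period class and canonical motif."""
    rows = [
        (x.period, x.canonical_motif, x.n_units)
        for x in loci
    ]
    if not rows:
        empty_p = pd.DataFrame(
            columns=["count", "proportion", "max_units", "mean_units"]
        ).rename_axis("period")
        empty_m = pd.DataFrame(columns=["count"]).rename_axis("canonical_motif")
        return CatalogSummary(period_table=empty_p, motif_table=empty_m, total=0)
    df = pd.DataFrame(rows, columns=["period", "canonical_motif", "n_units"])
    total = len(df)
    per = df.groupby("period")["n_units"].agg(
        count="size", max_units="max", mean_units="mean"
    )
    per["proportion"] = per["count"] / total
    if round_means is not None:
        per["mean_units"] = per["mean_units"].round(round_means)
    per = per[["count", "proportion", "max_units", "mean_units"]]
    motif = (
        df.groupby("canonical_motif")
        .size()
        .to_frame("count")
        .sort_values("count", ascending=False)
    )
    return CatalogSummary(period_table=per, motif_table=motif, total=total)
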