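"""Six-frame ORF finding with ambiguity-aware translation.

Transcript sequences assembled from mixed-platform reads carry ``N`` at
positions without read consensus.  Codons containing ``N`` translate to the
unknown residue ``X`` and — crucially — never terminate an open reading
frame, since an ``N``-containing codon might or might not be a stop.  ORF
length thresholds therefore count *effective* residues (non-``X``) by
default, while the reported residue count keeps ``X``.

Coordinates are 0-based half-open transcript coordinates throughout; the
coding span excludes the stop codon (BED-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

__all__ = [
    "Transcript",
    "OrfCall",
    "translate",
    "find_longest_orf",
    "enumerate_orf_candidates",
    "utr_intervals",
    "orf_length_stats",
    "TRANSCRIPT_ALPHABET",
]

TRANSCRIPT_ALPHABET = frozenset("ACGTN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA

_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class Transcript:
    """A contig / consensus nucleotide sequence with an identifier.

    The sequence is uppercased on construction and restricted to the
    alphabet ``{A, C, G, T, N}``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        seq = self.seq.upper()
        bad = set(seq) - TRANSCRIPT_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: illegal characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfCall:
    """Longest open reading frame called on a transcript.

    ``start``/``end`` delimit the coding span (start codon through the last
    sense codon, stop codon excluded) on the forward transcript coordinate
    system regardless of strand.  ``frame`` is the reading offset 0-2 on the
    scanned strand.  ``has_stop`` records whether the ORF terminated at an
    in-frame stop codon rather than at the sequence end.
    """

    transcript_id: str
    strand: Literal["+", "-"]
    frame: int
    start: int
    end: int
    aa_seq: str
    has_stop: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"bad frame {self.frame!r}")
        if not self.aa_seq.startswith("M"):
            raise ValueError("ORF translation must begin with M")
        if self.end - self.start != 3 * len(self.aa_seq):
            raise ValueError("coding span must be 3 * n_aa")

    @property
    def n_aa(self) -> int:
        return len(self.aa_seq)

    @property
    def n_x(self) -> int:
        return self.aa_seq.count("X")

    @property
    def effective_len(self) -> int:
        return self.n_aa - self.n_x


def translate(dna: str, offset: int = 0) -> str:
    """Translate ``dna`` from ``offset`` with the standard genetic code.

    Any codon containing a base outside ``{A,C,G,T}`` yields ``X``; stop
    codons are rendered as ``*``.  A trailing partial codon is ignored.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    dna = dna.upper()
    bad = set(dna) - TRANSCRIPT_ALPHABET
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)!r}")
    aas = []
    for i in range(offset, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def _frame_candidates(
    aa: str, frame: int, seq_len: int, strand: str, transcript_id: str
) -> Iterator[OrfCall]:
    """Candidates in one translated frame: first ATG of each inter-stop
    segment through that segment's stop (or frame end).

    Later ATGs in a segment yield strictly nested, shorter spans and can
    never be the unique longest call, so only the first is emitted.
    """
    n = len(aa)
    seg_start = 0
    while seg_start < n:
        stop_idx = aa.find("*", seg_start)
        seg_end = n if stop_idx == -1 else stop_idx
        m_idx = aa.find("M", seg_start, seg_end)
        if m_idx != -1:
            aa_sub = aa[m_idx:seg_end]
            s = frame + 3 * m_idx
            e = s + 3 * len(aa_sub)
            if strand == "+":
                start, end = s, e
            else:
                start, end = seq_len - e, seq_len - s
            yield OrfCall(
                transcript_id=transcript_id,
                strand=strand,  # type: ignore[arg-type]
                frame=frame,
                start=start,
                end=end,
                aa_seq=aa_sub,
                has_stop=stop_idx != -1,
            )
        if stop_idx == -1:
            break
        seg_start = stop_idx + 1


def enumerate_orf_candidates(
    t: Transcript,
    min_effective_aa: int = 20,
    strands: Literal["forward", "both"] = "both",
    count_x: bool = False,
) -> list[OrfCall]:
    """All qualifying ATG-anchored ORF candidates in deterministic order.

    Order: forward strand before reverse, then frame 0/1/2, then 5'→3' on
    the scanned strand.  ``count_x=True`` applies the length threshold to
    the total residue count instead of the effective (non-X) count.
    """
    out: list[OrfCall] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for strand in strand_list:
        seq = t.seq if strand == "+" else reverse_complement(t.seq)
        for frame in (0, 1, 2):
            aa = translate(seq, frame)
            for cand in _frame_candidates(aa, frame, len(seq), strand, t.id):
                length = cand.n_aa if count_x else cand.effective_len
                if length >= min_effective_aa:
                    out.append(cand)
    return out


def find_longest_orf(
    t: Transcript,
    min_effective_aa: int = 20,
    strands: Literal["forward", "both"] = "both",
    count_x: bool = False,
) -> OrfCall | None:
    """Longest qualifying ORF on ``t`` or ``None``.

    Candidates run from an ATG to the first in-frame stop codon or to the
    sequence end; codons containing ``N`` translate to ``X`` and do not
    terminate.  Among candidates whose effective length (non-X residues;
    total residues when ``count_x``) reaches ``min_effective_aa``, the one
    with the largest total residue count wins; ties break to forward
    strand, then lower frame index, then the leftmost start on the scanned
    strand.
    """
    best: OrfCall | None = None
    for cand in enumerate_orf_candidates(t, min_effective_aa, strands, count_x):
        if best is None or cand.n_aa > best.n_aa:
            best = cand
    return best


def utr_intervals(
    t: Transcript, orf: OrfCall
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(5'UTR, 3'UTR) intervals in forward transcript coordinates.

    The UTRs are defined in the ORF's reading orientation: the 5'UTR
    precedes the start codon and the 3'UTR follows the stop codon (or the
    coding span when no stop codon was reached).  Either may be empty.
    """
    if orf.transcript_id != t.id:
        raise ValueError(
            f"ORF transcript {orf.transcript_id!r} does not match {t.id!r}"
        )
    L = len(t)
    stop_len = 3 if orf.has_stop else 0
    if orf.strand == "+":
        utr5 = (0, orf.start)
        utr3 = (min(orf.end + stop_len, L), L)
    else:
        utr5 = (orf.end, L)
        utr3 = (0, max(orf.start - stop_len, 0))
    return utr5, utr3


@dataclass(frozen=True)
class OrfLengthStats:
    mean: float
    counts: np.ndarray
    bin_edges: np.ndarray
    n: int = field(default=0)


def orf_length_stats(
    orfs: Iterable[OrfCall],
    exclude_x: bool = False,
    bins: int | Sequence[float] = 30,
) -> OrfLengthStats:
    """Histogram and mean of ORF lengths in residues.

    With ``exclude_x`` the effective length (non-X residues) is used,
    mirroring a length comparison that discounts unknown residues.
    """
    lengths = np.array(
        [o.effective_len if exclude_x else o.n_aa for o in orfs], dtype=float
    )
    if lengths.size == 0:
        raise ValueError("orf_length_stats requires a non-empty collection")
    counts, edges = np.histogram(lengths, bins=bins)
    return OrfLengthStats(
        mean=float(lengths.mean()), counts=counts, bin_edges=edges, n=lengths.size
    )
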