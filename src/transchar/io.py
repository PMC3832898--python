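"""FASTA and TSV readers/writers for the characterization pipeline.

All tables are TSV with a header row; coordinates are 0-based half-open
everywhere.  Sequences are uppercased on ingest and ``U`` is mapped to
``T`` with a warning (RNA-style input).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orfs import OrfCall, Transcript, TRANSCRIPT_ALPHABET
from .ssr import SsrLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_orf_table",
    "write_orf_bed",
    "read_orf_table",
    "write_ssr_table",
    "read_ssr_table",
    "write_ssr_gff3",
]


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA; ids must be unique and sequences
    non-empty over ``{A,C,G,T,N}`` after uppercasing (U→T with warning)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: set[str] = set()
    out: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        if "U" in seq:
            warnings.warn(
                f"record {rec.id!r}: mapping U to T", stacklevel=2
            )
            seq = seq.replace("U", "T")
        bad = set(seq) - TRANSCRIPT_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has illegal characters "
                f"{sorted(bad)!r}"
            )
        out.append(Transcript(rec.id, seq))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(
    path: str | Path, transcripts: Iterable[Transcript], width: int = 80
) -> None:
    """Write transcripts as FASTA wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_ORF_COLUMNS = [
    "transcript_id",
    "strand",
    "frame",
    "start",
    "end",
    "n_aa",
    "n_x",
    "effective_len",
    "has_stop",
    "aa_seq",
]


def orf_table(orfs: Iterable[OrfCall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": o.transcript_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.start,
            "end": o.end,
            "n_aa": o.n_aa,
            "n_x": o.n_x,
            "effective_len": o.effective_len,
            "has_stop": o.has_stop,
            "aa_seq": o.aa_seq,
        }
        for o in orfs
    ]
    return pd.DataFrame(rows, columns=_ORF_COLUMNS)


def write_orf_table(path: str | Path, orfs: Iterable[OrfCall]) -> None:
    orf_table(orfs).to_csv(path, sep="\t", index=False)


def read_orf_table(path: str | Path) -> list[OrfCall]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    return [
        OrfCall(
            transcript_id=r.transcript_id,
            strand=r.strand,
            frame=int(r.frame),
            start=int(r.start),
            end=int(r.end),
            aa_seq=r.aa_seq,
            has_stop=bool(r.has_stop),
        )
        for r in df.itertuples(index=False)
    ]


def write_orf_bed(path: str | Path, orfs: Iterable[OrfCall]) -> None:
    """BED6: name is the transcript id, score is the effective length."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.start}\t{o.end}\t{o.transcript_id}\t"
                f"{o.effective_len}\t{o.strand}\n"
            )


_SSR_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "period",
    "motif",
    "canonical_motif",
    "n_units",
]


def ssr_table(loci: Iterable[SsrLocus]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": x.transcript_id,
            "start": x.start,
            "end": x.end,
            "period": x.period,
            "motif": x.motif,
            "canonical_motif": x.canonical_motif,
            "n_units": x.n_units,
        }
        for x in loci
    ]
    return pd.DataFrame(rows, columns=_SSR_COLUMNS)


def write_ssr_table(path: str | Path, loci: Iterable[SsrLocus]) -> None:
    ssr_table(loci).to_csv(path, sep="\t", index=False)


def read_ssr_table(path: str | Path) -> list[SsrLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    return [
        SsrLocus(
            transcript_id=r.transcript_id,
            start=int(r.start),
            end=int(r.end),
            period=int(r.period),
            motif=r.motif,
            canonical_motif=r.canonical_motif,
            n_units=int(r.n_units),
        )
        for r in df.itertuples(index=False)
    ]


def write_ssr_gff3(path: str | Path, loci: Iterable[SsrLocus]) -> None:
    """GFF3 with feature type ``microsatellite`` (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, x in enumerate(loci, 1):
            attrs = (
                f"ID=ssr{i};motif={x.motif};canonical_motif={x.canonical_motif};"
                f"n_units={x.n_units}"
            )
            fh.write(
                f"{x.transcript_id}\ttranschar\tmicrosatellite\t{x.start + 1}\t"
                f"{x.end}\t.\t+\t.\t{attrs}\n"
            )
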