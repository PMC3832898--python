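"""End-to-end transcript characterization: ORFs → SSRs → context →
summaries → optional GO enrichment.

Produces the tables behind a transcriptome characterization report: the
per-transcript longest-ORF calls with X accounting, the SSR catalog and
its period/motif summaries, region-labelled SSRs with region and
motif-by-region proportions, amino-acid homopolymer composition of
SSR-bearing ORF subsets, and — when an annotation table is supplied —
per-motif-class GO-term enrichment of SSR-bearing ORFs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .context import Region, classify_ssr, find_homopolymers, region_summary
from .enrichment import ssr_orf_enrichment
from .io import orf_table, read_fasta, ssr_table
from .orfs import OrfCall, Transcript, find_longest_orf, utr_intervals
from .ssr import SsrLocus, scan_ssrs, summarize_catalog

logger = logging.getLogger("transchar")

__all__ = ["PipelineConfig", "ReportBundle", "run_characterization", "write_report"]

_PERIOD_NAMES = {2: "di", 3: "tri", 4: "tetra"}


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches for the characterization pipeline."""

    min_effective_aa: int = 20
    ssr_periods: tuple[int, ...] = (2, 3, 4)
    min_units: int = 5
    strands: str = "both"
    homopolymer_min_len: int = 5
    alpha: float = 0.05
    sided: str = "greater"
    count_x: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_effective_aa < 1 or self.min_units < 1:
            raise ValueError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.strands not in ("forward", "both"):
            raise ValueError(f"strands must be 'forward' or 'both'")


@dataclass
class ReportBundle:
    """All tables produced by one characterization run."""

    orfs: pd.DataFrame
    ssrs: pd.DataFrame
    labeled_ssrs: pd.DataFrame
    region_table: pd.DataFrame
    region_by_period: pd.DataFrame
    period_summary: pd.DataFrame
    motif_summary: pd.DataFrame
    homopolymers: pd.DataFrame
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_characterization(
    fasta: str | Path | Sequence[Transcript],
    config: PipelineConfig = PipelineConfig(),
    annotations: Iterable[tuple[str, str]] | None = None,
) -> ReportBundle:
    """Characterize a transcript set end to end; deterministic for fixed
    inputs and configuration."""
    t0 = time.monotonic()
    meta: dict = {"version": __version__, "config": dataclasses_dict(config)}
    if isinstance(fasta, (str, Path)):
        transcripts = read_fasta(fasta)
        meta["input"] = str(fasta)
        meta["input_sha256"] = _checksum(fasta)
    else:
        transcripts = list(fasta)
    logger.info("loaded %d transcripts", len(transcripts))

    orfs: dict[str, OrfCall] = {}
    for t in transcripts:
        call = find_longest_orf(
            t,
            min_effective_aa=config.min_effective_aa,
            strands=config.strands,  # type: ignore[arg-type]
            count_x=config.count_x,
        )
        if call is not None:
            orfs[t.id] = call
    logger.info(
        "ORF stage: %d/%d transcripts with a qualifying ORF (%.1fs)",
        len(orfs), len(transcripts), time.monotonic() - t0,
    )

    loci: list[SsrLocus] = []
    for t in transcripts:
        loci.extend(scan_ssrs(t, periods=config.ssr_periods, min_units=config.min_units))
    logger.info("SSR stage: %d loci", len(loci))

    labeled = [
        (x, classify_ssr(x, orfs.get(x.transcript_id))) for x in loci
    ]
    ssr_df = ssr_table(loci)
    labeled_df = ssr_df.copy()
    labeled_df["region"] = [str(reg) for _, reg in labeled]

    region_df, by_period_df = region_summary(labeled)
    catalog = summarize_catalog(loci)

    homopolymer_rows = []
    ssr_orf_ids = _ssr_orf_ids(labeled)
    for cls, ids in ssr_orf_ids.items():
        subset = {tid: orfs[tid].aa_seq for tid in sorted(ids) if tid in orfs}
        for tid, aa in subset.items():
            for run in find_homopolymers(
                aa, min_len=config.homopolymer_min_len, orf_id=tid
            ):
                homopolymer_rows.append(
                    {
                        "motif_class": cls,
                        "orf_id": run.orf_id,
                        "residue": run.residue,
                        "length": run.length,
                        "start": run.start,
                    }
                )
    homopolymer_df = pd.DataFrame(
        homopolymer_rows,
        columns=["motif_class", "orf_id", "residue", "length", "start"],
    )

    enrich: dict[str, pd.DataFrame] = {}
    if annotations is not None:
        enrich = ssr_orf_enrichment(
            annotations,
            {k: v for k, v in ssr_orf_ids.items() if v},
            alpha=config.alpha,
            sided=config.sided,
        )
        logger.info("enrichment stage: %d motif classes tested", len(enrich))

    meta["n_transcripts"] = len(transcripts)
    meta["n_orfs"] = len(orfs)
    meta["n_ssrs"] = len(loci)
    meta["elapsed_s"] = round(time.monotonic() - t0, 3)
    return ReportBundle(
        orfs=orf_table(orfs.values()),
        ssrs=ssr_df,
        labeled_ssrs=labeled_df,
        region_table=region_df.reset_index(),
        region_by_period=by_period_df,
        period_summary=catalog.period_table.reset_index(),
        motif_summary=catalog.motif_table.reset_index(),
        homopolymers=homopolymer_df,
        enrichment=enrich,
        metadata=meta,
    )


def _ssr_orf_ids(
    labeled: Sequence[tuple[SsrLocus, Region]]
) -> dict[str, set[str]]:
    """Transcript ids whose coding span carries each repeat class."""
    out: dict[str, set[str]] = {"di": set(), "tri": set(), "tetra": set()}
    for x, reg in labeled:
        if reg is Region.ORF:
            out[_PERIOD_NAMES[x.period]].add(x.transcript_id)
    return out


def dataclasses_dict(cfg: PipelineConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write every table of the bundle as TSV plus a JSON metadata file."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "orfs.tsv": bundle.orfs,
        "ssrs.tsv": bundle.ssrs,
        "ssrs_labeled.tsv": bundle.labeled_ssrs,
        "region_summary.tsv": bundle.region_table,
        "region_by_period.tsv": bundle.region_by_period,
        "period_summary.tsv": bundle.period_summary,
        "motif_summary.tsv": bundle.motif_summary,
        "homopolymers.tsv": bundle.homopolymers,
    }
    for name, df in tables.items():
        df.to_csv(out / name, sep="\t", index=False, float_format="%.6g")
    for cls, df in bundle.enrichment.items():
        df.to_csv(out / f"enrichment_{cls}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, default=str)
        fh.write("\n")


def utr_table(
    transcripts: Sequence[Transcript], orfs: dict[str, OrfCall]
) -> pd.DataFrame:
    """5'/3' UTR intervals per ORF-bearing transcript."""
    rows = []
    for t in transcripts:
        call = orfs.get(t.id)
        if call is None:
            continue
        (u5s, u5e), (u3s, u3e) = utr_intervals(t, call)
        rows.append(
            {
                "transcript_id": t.id,
                "utr5_start": u5s,
                "utr5_end": u5e,
                "utr3_start": u3s,
                "utr3_end": u3e,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "utr5_start", "utr5_end", "utr3_start", "utr3_end"],
    )
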