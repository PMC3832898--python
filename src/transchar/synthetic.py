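"""Synthetic transcript cohorts with planted, machine-readable truth.

Generates transcript-like sequences that emulate mixed-platform consensus
contigs: a planted ORF (ATG .. stop) on a known strand, perfect
di/tri/tetranucleotide repeats planted in a controlled genomic context
(inside the ORF, in either UTR, straddling an ORF boundary, or on a
non-coding transcript), runs of ``N`` emulating zero-coverage consensus
sites, and GO-term assignments with a controllable enrichment effect in a
designated ORF subset.  Everything downstream of the assembler can then be
tested against exact planted truth.

Guards keep the truth tables exact: flanking bases never extend a planted
repeat, incidental repeats of five or more units are rejected and redrawn,
competitor ORFs as long as the planted one are mutated away, and ``N``
runs never touch a planted start or stop codon.  Non-coding transcripts
are generated free of ATG/CAT trigrams so that no qualifying ORF can
exist on either strand.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from .context import Region
from .orfs import OrfCall, Transcript, enumerate_orf_candidates, find_longest_orf
from .ssr import canonical_motif, is_primitive, scan_ssrs

__all__ = [
    "SsrPlanEntry",
    "EnrichmentEffect",
    "SynthConfig",
    "PlantedOrf",
    "PlantedSsr",
    "TruthSet",
    "SynthesisError",
    "generate_transcripts",
    "generate_annotation_table",
    "write_synthetic_dataset",
]

_STOPS = ("TAA", "TAG", "TGA")
_START = "ATG"
_START_RC = "CAT"
_MAX_ATTEMPTS = 400
_MAX_SUPPRESS_ITERS = 40


class SynthesisError(ValueError):
    """Configuration or construction failure in the synthetic generator."""


@dataclass(frozen=True)
class SsrPlanEntry:
    """One repeat to plant: motif, complete-unit count and target region."""

    motif: str
    n_units: int
    region: Region

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if not 2 <= len(motif) <= 4:
            raise SynthesisError(f"planted motif {motif!r} must be 2-4 bp")
        if not is_primitive(motif):
            raise SynthesisError(f"planted motif {motif!r} is not primitive")
        if self.n_units < 1:
            raise SynthesisError("n_units must be >= 1")


@dataclass(frozen=True)
class EnrichmentEffect:
    """Designated term assigned with probability ``p_target`` inside the
    target ORF subset and ``p_background`` elsewhere."""

    term: str
    p_target: float
    p_background: float
    target_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for p in (self.p_target, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise SynthesisError(f"effect probability {p} outside [0,1]")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate mid-size transcriptome contigs: 0.3-1.5 kb
    transcripts at 45% GC, half of them carrying a 30-150 codon ORF, and
    sparse zero-coverage N runs (0.2 per kb, 2-15 bp).
    """

    n_transcripts: int = 100
    length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.45
    orf_prob: float = 0.5
    orf_length_range: tuple[int, int] = (30, 150)
    ssr_plan: tuple[SsrPlanEntry, ...] = ()
    n_run_rate: float = 0.2
    n_run_length_range: tuple[int, int] = (2, 15)
    go_terms: tuple[str, ...] = ()
    enrichment_effect: EnrichmentEffect | None = None
    background_term_prob: float = 0.1
    seed: int = 0
    min_orf_aa: int = 20
    reverse_strand_prob: float = 0.0
    suppress_incidental_ssrs: bool = True
    utr_margin: int = 12

    def __post_init__(self) -> None:
        self.ssr_plan = tuple(
            e if isinstance(e, SsrPlanEntry) else SsrPlanEntry(*e)
            for e in self.ssr_plan
        )
        if self.n_transcripts < 1:
            raise SynthesisError("n_transcripts must be positive")
        for name, prob in (
            ("gc_content", self.gc_content),
            ("orf_prob", self.orf_prob),
            ("reverse_strand_prob", self.reverse_strand_prob),
            ("background_term_prob", self.background_term_prob),
        ):
            if not 0.0 <= prob <= 1.0:
                raise SynthesisError(f"{name}={prob} outside [0,1]")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SynthesisError(f"degenerate length_range {self.length_range}")
        olo, ohi = self.orf_length_range
        if not self.min_orf_aa <= olo <= ohi:
            raise SynthesisError(
                f"orf_length_range {self.orf_length_range} must start at or "
                f"above min_orf_aa={self.min_orf_aa}"
            )
        if self.n_run_rate < 0:
            raise SynthesisError("n_run_rate must be non-negative")
        # smallest transcript must fit the smallest ORF plus stop and margins
        if hi < 3 * olo + 3 + 2 * self.utr_margin:
            raise SynthesisError(
                "length_range too short for the configured ORF lengths"
            )


@dataclass(frozen=True)
class PlantedOrf:
    transcript_id: str
    strand: str
    start: int
    end: int  # coding span, stop codon excluded


@dataclass(frozen=True)
class PlantedSsr:
    transcript_id: str
    start: int
    end: int
    motif: str
    n_units: int
    region: Region


@dataclass
class TruthSet:
    """Planted truth emitted alongside a synthetic cohort."""

    planted_orfs: list[PlantedOrf] = field(default_factory=list)
    planted_ssrs: list[PlantedSsr] = field(default_factory=list)
    term_table: list[tuple[str, str]] = field(default_factory=list)

    def orf_for(self, transcript_id: str) -> PlantedOrf | None:
        for o in self.planted_orfs:
            if o.transcript_id == transcript_id:
                return o
        return None

    def ssr_orf_ids_by_period(self) -> dict[str, set[str]]:
        """ORF-bearing transcript ids per repeat period class, for SSRs
        planted inside the coding span."""
        with_orf = {o.transcript_id for o in self.planted_orfs}
        out: dict[str, set[str]] = {"di": set(), "tri": set(), "tetra": set()}
        names = {2: "di", 3: "tri", 4: "tetra"}
        for s in self.planted_ssrs:
            if s.region is Region.ORF and s.transcript_id in with_orf:
                out[names[len(s.motif)]].add(s.transcript_id)
        return out


# ---------------------------------------------------------------------------
# sequence-building helpers


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    at = (1.0 - gc) / 2.0
    gcp = gc / 2.0
    idx = rng.choice(4, size=n, p=[at, gcp, gcp, at])
    lut = "ACGT"
    return [lut[i] for i in idx]


def _window_has_signal(seq: list[str], pos: int, signals=(_START, _START_RC)) -> bool:
    lo = max(0, pos - 2)
    hi = min(len(seq), pos + 3)
    s = "".join(seq[lo:hi])
    return any(sig in s for sig in signals)


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(lo <= pos < hi for lo, hi in intervals)


def _scrub_signals(
    seq: list[str],
    rng: np.random.Generator,
    protected: list[tuple[int, int]],
) -> bool:
    """Remove every ATG/CAT trigram whose window is editable, by resampling
    one unprotected base of the window.  True on success."""
    for _ in range(8):
        dirty = False
        s = "".join(seq)
        for sig in (_START, _START_RC):
            start = s.find(sig)
            while start != -1:
                editable = [
                    p for p in range(start, start + 3) if not _in_any(p, protected)
                ]
                if not editable:
                    return False
                dirty = True
                pos = editable[int(rng.integers(len(editable)))]
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(len(choices)))]
                s = "".join(seq)
                start = s.find(sig, start + 1)
        if not dirty:
            return True
    return _scrub_ok(seq)


def _scrub_ok(seq: list[str]) -> bool:
    s = "".join(seq)
    return _START not in s and _START_RC not in s


def _random_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = "".join(_draw_bases(rng, 3, gc))
        if codon not in _STOPS:
            return codon


def _codon_start(pos: int, orf_start: int) -> int:
    return orf_start + 3 * ((pos - orf_start) // 3)


def _planted_codons_ok(
    seq: list[str], lo: int, hi: int, orf_start: int, orf_end: int
) -> bool:
    """No stop codon among planted-frame codons overlapping [lo, hi)."""
    c = max(orf_start, _codon_start(lo, orf_start))
    while c < min(orf_end, hi + 2):
        if c + 3 <= len(seq) and "".join(seq[c : c + 3]) in _STOPS:
            return False
        c += 3
    return True


# ---------------------------------------------------------------------------
# straddle feasibility

def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def _straddle5_solution(motif: str, n_units: int) -> tuple[str, int] | None:
    """(rotation, k): repeat suffix of length k supplies 'ATG'[:k].

    Conservative feasibility: the repeat must not contain an ATG other
    than a designed k=3 suffix (an in-frame upstream ATG inside the
    protected repeat could not be suppressed).
    """
    p = len(motif)
    for rot in _rotations(motif):
        R = rot * n_units
        for k in (1, 2, 3):
            if k >= len(R):
                continue
            if R[-k:] != _START[:k]:
                continue
            if k < 3 and _START[k] == R[-p]:
                continue  # flank after the repeat would extend it
            body = R[:-3] if k == 3 else R
            if _START in body:
                continue
            return rot, k
    return None


def _straddle3_solution(motif: str, n_units: int) -> tuple[str, int, str] | None:
    """(rotation, k, stop): repeat suffix of length k supplies stop[:k],
    and the repeat's coding part is stop-free at the implied phase.

    The phase of the repeat start relative to the codon grid is fixed by
    geometry: phi = (k - p*n_units) mod 3.  The repeat must not contain a
    CAT trigram (a reverse-strand start inside the protected repeat).
    """
    p = len(motif)
    for rot in _rotations(motif):
        R = rot * n_units
        if _START_RC in R:
            continue
        for stop in _STOPS:
            for k in (1, 2, 3):
                if k >= len(R):
                    continue
                if R[-k:] != stop[:k]:
                    continue
                if k < 3 and stop[k] == R[-p]:
                    continue
                # coding part of the repeat is R[:-k]; first full codon
                # starts at offset (3 - phi) % 3 where phi = (k - len(R)) % 3
                off = (len(R) - k) % 3
                off = (3 - off) % 3 if off else 0
                coding = R[: len(R) - k]
                if any(
                    coding[i : i + 3] in _STOPS
                    for i in range(off, len(coding) - 2, 3)
                ):
                    continue
                return rot, k, stop
    return None


# ---------------------------------------------------------------------------
# competitor-ORF suppression


def _kill_candidate(
    seq: list[str],
    cand: OrfCall,
    protected: list[tuple[int, int]],
    orf_span: tuple[int, int] | None,
    rng: np.random.Generator,
) -> bool:
    """Mutate one base of a competitor ORF's start codon so that it is no
    longer a start, without breaking planted structure.  Falls back to
    inserting a stop into the competitor's frame when the start codon is
    protected.  True if a mutation was applied."""
    if cand.strand == "+":
        codon_iv = (cand.start, cand.start + 3)
        signal = _START
    else:
        codon_iv = (cand.end - 3, cand.end)
        signal = _START_RC

    def try_edit(pos: int, base: str) -> bool:
        old = seq[pos]
        if old == base:
            return False
        seq[pos] = base
        lo, hi = max(0, pos - 2), min(len(seq), pos + 3)
        window = "".join(seq[lo:hi])
        ok = _START not in window and _START_RC not in window
        if ok and orf_span is not None:
            s0, e0 = orf_span
            if s0 <= pos < e0:
                ok = _planted_codons_ok(seq, pos, pos + 1, s0, e0)
        if ok:
            return True
        seq[pos] = old
        return False

    positions = [p for p in range(*codon_iv) if not _in_any(p, protected)]
    order = list(rng.permutation(len(positions)))
    for pi in order:
        pos = positions[pi]
        for base in "ACGT":
            if try_edit(pos, base):
                if "".join(seq[codon_iv[0] : codon_iv[1]]) != signal:
                    return True
                # start codon survived (edit changed a neighbor view); revert
                # handled by try_edit semantics — base change inside codon
                # always changes the trigram, so this is unreachable.
    # start codon fully protected: write a stop codon into the competitor's
    # frame at an editable codon position
    span = range(cand.start, cand.end - 2, 3)
    if cand.strand == "-":
        span = range(cand.end - 3, cand.start - 1, -3)
    for cpos in span:
        if any(_in_any(p, protected) for p in range(cpos, cpos + 3)):
            continue
        stop = "TAA" if cand.strand == "+" else "TTA"  # revcomp(TAA)
        old = seq[cpos : cpos + 3]
        seq[cpos : cpos + 3] = list(stop)
        lo, hi = max(0, cpos - 2), min(len(seq), cpos + 5)
        window = "".join(seq[lo:hi])
        ok = _START not in window and _START_RC not in window
        if ok and orf_span is not None and orf_span[0] <= cpos < orf_span[1]:
            ok = _planted_codons_ok(seq, cpos, cpos + 3, *orf_span)
        if ok:
            return True
        seq[cpos : cpos + 3] = old
    return False


def _suppress_competitors(
    seq: list[str],
    tid: str,
    planted: PlantedOrf,
    protected: list[tuple[int, int]],
    min_aa: int,
    rng: np.random.Generator,
) -> bool:
    """Mutate away every ORF candidate at least as long as the planted one.

    The planted coding span itself may be edited as long as its in-frame
    codons stay sense codons; start/stop codons and planted repeats are in
    ``protected`` and never touched.
    """
    planted_len = (planted.end - planted.start) // 3
    key = (planted.strand, planted.start, planted.end)
    for _ in range(_MAX_SUPPRESS_ITERS):
        t = Transcript(tid, "".join(seq))
        cands = enumerate_orf_candidates(t, min_effective_aa=min_aa)
        rivals = [
            c
            for c in cands
            if (c.strand, c.start, c.end) != key and c.n_aa >= planted_len
        ]
        if not rivals:
            return True
        progress = False
        for c in rivals:
            if _kill_candidate(
                seq, c, protected, (planted.start, planted.end), rng
            ):
                progress = True
        if not progress:
            return False
    return False


# ---------------------------------------------------------------------------
# per-transcript construction


def _fix_repeat_flanks(
    seq: list[str],
    s: int,
    e: int,
    p: int,
    frozen: list[tuple[int, int]],
    orf_span: tuple[int, int] | None,
    rng: np.random.Generator,
    scrubbed: bool,
) -> bool:
    """Ensure the planted run is maximal exactly at [s, e): the base before
    and after must break the period.  Edits respect frozen intervals and
    keep planted in-frame codons sense codons."""
    for pos, partner in (((s - 1), (s - 1 + p)), (e, e - p)):
        if not 0 <= pos < len(seq):
            continue
        if seq[pos] != seq[partner]:
            continue
        if _in_any(pos, frozen):
            return False
        choices = [b for b in "ACGT" if b != seq[partner]]
        ok = False
        for bi in rng.permutation(len(choices)):
            base = choices[int(bi)]
            old = seq[pos]
            seq[pos] = base
            good = True
            if scrubbed and _window_has_signal(seq, pos):
                good = False
            if good and orf_span is not None and orf_span[0] <= pos < orf_span[1]:
                good = _planted_codons_ok(seq, pos, pos + 1, *orf_span)
            if good:
                ok = True
                break
            seq[pos] = old
        if not ok:
            return False
    return True


def _place_n_runs(
    seq: list[str],
    cfg: SynthConfig,
    forbidden: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    L = len(seq)
    n_runs = int(rng.poisson(cfg.n_run_rate * L / 1000.0))
    lo, hi = cfg.n_run_length_range
    for _ in range(n_runs):
        run_len = int(rng.integers(lo, hi + 1))
        for _try in range(20):
            start = int(rng.integers(0, max(1, L - run_len)))
            iv = (start, start + run_len)
            if any(iv[0] < f_hi and iv[1] > f_lo for f_lo, f_hi in forbidden):
                continue
            seq[iv[0] : iv[1]] = ["N"] * run_len
            break


def _build_one(
    tid: str,
    has_orf: bool,
    entry: SsrPlanEntry | None,
    reverse: bool,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[str, PlantedOrf | None, PlantedSsr | None]:
    """Assemble one transcript; raises SynthesisError when the plan entry is
    structurally infeasible, retries internally on stochastic failures."""
    straddle5 = straddle3 = None
    if entry is not None:
        region = entry.region
        if region in (Region.UTR5, Region.UTR3, Region.STRADDLE5, Region.STRADDLE3, Region.ORF):
            if not has_orf:
                raise SynthesisError(
                    f"{region} repeat requested on a transcript without an ORF"
                )
        if region is Region.NONCODING:
            R = entry.motif * entry.n_units
            if _START in R or _START_RC in R:
                raise SynthesisError(
                    f"NONCODING repeat {entry.motif!r} x{entry.n_units} contains "
                    "ATG/CAT and cannot be planted on an ORF-free transcript"
                )
        if region is Region.STRADDLE5:
            straddle5 = _straddle5_solution(entry.motif, entry.n_units)
            if straddle5 is None:
                raise SynthesisError(
                    f"motif {entry.motif!r} cannot straddle an ORF start"
                )
        if region is Region.STRADDLE3:
            straddle3 = _straddle3_solution(entry.motif, entry.n_units)
            if straddle3 is None:
                raise SynthesisError(
                    f"motif {entry.motif!r} cannot straddle an ORF stop"
                )

    margin = cfg.utr_margin
    for _attempt in range(_MAX_ATTEMPTS):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = _draw_bases(rng, L, cfg.gc_content)
        orf: PlantedOrf | None = None
        ssr: PlantedSsr | None = None
        frozen: list[tuple[int, int]] = []  # never edited by guards
        ssr_protected: list[tuple[int, int]] = []

        if has_orf:
            olo, ohi = cfg.orf_length_range
            fit = (L - 3 - 2 * margin) // 3
            if fit < olo:
                continue
            n_codons = int(rng.integers(olo, min(ohi, fit) + 1))
            span_nt = 3 * n_codons
            # region-driven geometry constraints on the start position
            lo_start, hi_start = margin, L - span_nt - 3 - margin
            if entry is not None:
                need = len(entry.motif) * entry.n_units + 2
                if entry.region is Region.UTR5:
                    lo_start = max(lo_start, need + 7)
                elif entry.region is Region.UTR3:
                    hi_start = min(hi_start, L - span_nt - 3 - need - 2)
                elif entry.region is Region.STRADDLE5:
                    p = len(entry.motif)
                    lo_start = max(lo_start, p * entry.n_units - straddle5[1] + 1)
                elif entry.region is Region.ORF:
                    if span_nt - 6 < len(entry.motif) * entry.n_units + 2:
                        continue
            if lo_start > hi_start:
                continue
            orf_start = int(rng.integers(lo_start, hi_start + 1))
            orf_end = orf_start + span_nt
            seq[orf_start : orf_start + 3] = list(_START)
            for c in range(orf_start + 3, orf_end, 3):
                seq[c : c + 3] = list(_random_sense_codon(rng, cfg.gc_content))
            stop = _STOPS[int(rng.integers(3))]
            seq[orf_end : orf_end + 3] = list(stop)
            orf = PlantedOrf(tid, "+", orf_start, orf_end)
            frozen += [(orf_start, orf_start + 3), (orf_end, orf_end + 3)]

        if entry is not None:
            p = len(entry.motif)
            nu = entry.n_units
            rep_len = p * nu
            if entry.region is Region.NONCODING:
                s = int(rng.integers(1, L - rep_len))
                R = entry.motif * nu
            elif entry.region is Region.UTR5:
                s = int(rng.integers(1, orf.start - rep_len - 6))
                R = entry.motif * nu
            elif entry.region is Region.UTR3:
                lo_s = orf.end + 4
                s = int(rng.integers(lo_s, L - rep_len))
                R = entry.motif * nu
            elif entry.region is Region.ORF:
                rot_order = rng.permutation(p)
                placed = False
                for _try in range(60):
                    rot = _rotations(entry.motif)[int(rot_order[_try % p])]
                    R = rot * nu
                    s = int(rng.integers(orf.start + 4, orf.end - rep_len - 1))
                    old = seq[s : s + rep_len]
                    seq[s : s + rep_len] = list(R)
                    if _planted_codons_ok(seq, s, s + rep_len, orf.start, orf.end):
                        placed = True
                        break
                    seq[s : s + rep_len] = old
                if not placed:
                    continue
            elif entry.region is Region.STRADDLE5:
                rot, k = straddle5
                R = rot * nu
                e = orf.start + k
                s = e - rep_len
                if s < 1:
                    continue
            else:  # STRADDLE3
                rot, k, stop3 = straddle3
                R = rot * nu
                e = orf.end + k
                s = e - rep_len
                if s < orf.start + 4:
                    continue
                seq[orf.end : orf.end + 3] = list(stop3)

            seq[s : s + rep_len] = list(R)
            e = s + rep_len
            if entry.region is Region.STRADDLE3:
                # left junction codon may straddle background/repeat; keep it
                # a sense codon
                c0 = _codon_start(s, orf.start)
                if c0 < s:
                    for _try in range(20):
                        if _planted_codons_ok(seq, c0, s, orf.start, orf.end):
                            break
                        for ppos in range(c0, s):
                            seq[ppos] = _draw_bases(rng, 1, cfg.gc_content)[0]
                    else:
                        continue
            ssr = PlantedSsr(tid, s, e, R[:p], nu, entry.region)
            ssr_protected.append((s, e))
            frozen.append((s, e))

        protected = frozen + ssr_protected
        scrubbed = False
        if not has_orf:
            if not _scrub_signals(seq, rng, protected):
                continue
            scrubbed = True

        if has_orf:
            if not _suppress_competitors(
                seq, tid, orf, protected, cfg.min_orf_aa, rng
            ):
                continue

        if ssr is not None:
            if not _fix_repeat_flanks(
                seq,
                ssr.start,
                ssr.end,
                len(ssr.motif),
                frozen,
                (orf.start, orf.end) if orf else None,
                rng,
                scrubbed,
            ):
                continue

        n_forbidden = list(ssr_protected)
        if orf is not None:
            n_forbidden += [(orf.start, orf.start + 3), (orf.end, orf.end + 3)]
        _place_n_runs(seq, cfg, n_forbidden, rng)

        # orient
        if reverse and orf is not None:
            seq = list(reverse_complement("".join(seq)))
            o_start, o_end = L - orf.end, L - orf.start
            orf = PlantedOrf(tid, "-", o_start, o_end)
            if ssr is not None:
                s2, e2 = L - ssr.end, L - ssr.start
                ssr = PlantedSsr(
                    tid, s2, e2, "".join(seq[s2 : s2 + len(ssr.motif)]),
                    ssr.n_units, ssr.region,
                )

        # final verification against the package's own scanners
        t = Transcript(tid, "".join(seq))
        if cfg.suppress_incidental_ssrs:
            found = scan_ssrs(t)
            want = (
                []
                if ssr is None
                else [(ssr.start, ssr.end, canonical_motif(ssr.motif), ssr.n_units)]
            )
            got = [(x.start, x.end, x.canonical_motif, x.n_units) for x in found]
            if got != want:
                continue
        if orf is not None:
            call = find_longest_orf(t, min_effective_aa=cfg.min_orf_aa)
            if (
                call is None
                or (call.strand, call.start, call.end)
                != (orf.strand, orf.start, orf.end)
            ):
                continue
        elif not _scrub_ok(seq):
            continue
        return t.seq, orf, ssr

    raise SynthesisError(
        f"could not assemble transcript {tid!r} after {_MAX_ATTEMPTS} attempts"
    )


# ---------------------------------------------------------------------------
# public API


def generate_transcripts(
    config: SynthConfig,
) -> tuple[list[Transcript], TruthSet]:
    """Generate a transcript cohort and its exact planted truth.

    Deterministic for a fixed seed.  Every ``ssr_plan`` entry is realized
    on its own transcript as a perfect repeat of the stated motif class and
    unit count, in the stated region; regions that require an ORF raise a
    :class:`SynthesisError` when no ORF-bearing transcript is available.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_transcripts
    has_orf = rng.random(n) < cfg.orf_prob
    reverse = rng.random(n) < cfg.reverse_strand_prob

    need_orf = [e.region is not Region.NONCODING for e in cfg.ssr_plan]
    orf_pool = [i for i in range(n) if has_orf[i]]
    nc_pool = [i for i in range(n) if not has_orf[i]]
    if sum(need_orf) > len(orf_pool):
        raise SynthesisError(
            f"{sum(need_orf)} ORF-context repeats planned but only "
            f"{len(orf_pool)} transcripts drew an ORF (orf_prob={cfg.orf_prob})"
        )
    if (len(need_orf) - sum(need_orf)) > len(nc_pool):
        raise SynthesisError(
            "more NONCODING repeats planned than ORF-free transcripts"
        )
    orf_pick = list(rng.permutation(orf_pool))
    nc_pick = list(rng.permutation(nc_pool))
    assignment: dict[int, SsrPlanEntry] = {}
    for e, needs in zip(cfg.ssr_plan, need_orf):
        idx = orf_pick.pop() if needs else nc_pick.pop()
        assignment[int(idx)] = e

    width = len(str(n))
    transcripts: list[Transcript] = []
    truth = TruthSet()
    for i in range(n):
        tid = f"synth{i:0{width}d}"
        seq, orf, ssr = _build_one(
            tid,
            bool(has_orf[i]),
            assignment.get(i),
            bool(reverse[i]) and bool(has_orf[i]),
            cfg,
            rng,
        )
        transcripts.append(Transcript(tid, seq))
        if orf is not None:
            truth.planted_orfs.append(orf)
        if ssr is not None:
            truth.planted_ssrs.append(ssr)

    if cfg.go_terms or cfg.enrichment_effect is not None:
        truth.term_table = generate_annotation_table(
            truth,
            cfg.enrichment_effect,
            seed=int(rng.integers(2**31 - 1)),
            extra_terms=cfg.go_terms,
            background_prob=cfg.background_term_prob,
        )
    return transcripts, truth


def generate_annotation_table(
    truth: TruthSet,
    effect: EnrichmentEffect | None,
    seed: int,
    extra_terms: tuple[str, ...] = (),
    background_prob: float = 0.1,
) -> list[tuple[str, str]]:
    """(orf_id, term_id) pairs with a planted enrichment effect.

    The designated term is assigned to target-subset ORFs with probability
    ``p_target`` and elsewhere with ``p_background``; every term in
    ``extra_terms`` is assigned independently with ``background_prob``.
    ORF ids are the transcript ids (one ORF per transcript).  The default
    target subset is the ORFs carrying a planted trinucleotide repeat
    inside the coding span.
    """
    orf_ids = [o.transcript_id for o in truth.planted_orfs]
    if not orf_ids:
        raise SynthesisError("annotation table requires at least one planted ORF")
    rng = np.random.default_rng(seed)
    table: list[tuple[str, str]] = []
    if effect is not None:
        if effect.target_ids is not None:
            targets = set(effect.target_ids)
        else:
            targets = truth.ssr_orf_ids_by_period()["tri"]
        for oid in orf_ids:
            p = effect.p_target if oid in targets else effect.p_background
            if rng.random() < p:
                table.append((oid, effect.term))
    for term in extra_terms:
        if effect is not None and term == effect.term:
            continue
        for oid in orf_ids:
            if rng.random() < background_prob:
                table.append((oid, term))
    return table


def write_synthetic_dataset(
    outdir: str | Path,
    transcripts: list[Transcript],
    truth: TruthSet,
    config: SynthConfig,
) -> None:
    """Write FASTA, truth TSVs (0-based half-open coordinates) and a JSON
    sidecar echoing the full configuration including the seed."""
    from .io import write_fasta  # local import to avoid a cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "transcripts.fasta", transcripts)
    with open(out / "truth_orfs.tsv", "w") as fh:
        fh.write("transcript_id\tstrand\tstart\tend\n")
        for o in truth.planted_orfs:
            fh.write(f"{o.transcript_id}\t{o.strand}\t{o.start}\t{o.end}\n")
    with open(out / "truth_ssrs.tsv", "w") as fh:
        fh.write("transcript_id\tstart\tend\tmotif\tn_units\tregion\n")
        for s in truth.planted_ssrs:
            fh.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.motif}\t"
                f"{s.n_units}\t{s.region}\n"
            )
    with open(out / "truth_terms.tsv", "w") as fh:
        fh.write("orf_id\tterm_id\n")
        for oid, term in truth.term_table:
            fh.write(f"{oid}\t{term}\n")
    cfg = dataclasses.asdict(config)
    cfg["ssr_plan"] = [
        {"motif": e.motif, "n_units": e.n_units, "region": str(e.region)}
        for e in config.ssr_plan
    ]
    if config.enrichment_effect is not None:
        cfg["enrichment_effect"] = dataclasses.asdict(config.enrichment_effect)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
        fh.write("\n")
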