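"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's scanning code paths: the ORF oracle
enumerates every ATG-anchored span in all six frames via Biopython
translation of raw slices; the SSR oracle extends runs by indexing into
the motif; the Fisher oracle enumerates every 2x2 table with the observed
margins using exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from Bio.Seq import Seq, reverse_complement

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str, min_effective_aa: int = 20, strands: str = "both"):
    """(strand, start, end, aa_seq) of the longest qualifying ORF, or None.

    Enumerates every ATG in every frame on the requested strands,
    translating with Biopython; a candidate runs to the first in-frame
    '*' or the sequence end.  Ties break to forward strand, lower frame,
    leftmost start on the scanned strand.
    """
    candidates = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    L = len(seq)
    for strand in strand_list:
        s = seq if strand == "+" else reverse_complement(seq)
        for i in range(L - 2):
            if s[i : i + 3] != "ATG":
                continue
            n_codons = (L - i) // 3
            sub = s[i : i + 3 * n_codons]
            aa = str(Seq(sub).translate())
            # the consensus convention: any codon containing N is an unknown
            # residue (Biopython would resolve four-fold degenerate codons)
            aa = "".join(
                "X" if "N" in sub[3 * j : 3 * j + 3] else ch
                for j, ch in enumerate(aa)
            )
            stop = aa.find("*")
            aa = aa if stop == -1 else aa[:stop]
            if len(aa) - aa.count("X") < min_effective_aa:
                continue
            e_s = i + 3 * len(aa)
            if strand == "+":
                start, end = i, e_s
            else:
                start, end = L - e_s, L - i
            candidates.append(
                (len(aa), strand, i % 3, i, start, end, aa)
            )
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1] != "+", c[2], c[3]))
    best = candidates[0]
    return best[1], best[4], best[5], best[6]


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_ssrs(seq: str, periods=(2, 3, 4), min_units: int = 5):
    """All (start, end, period, motif, n_units) loci, left-to-right greedy
    per period, extending runs by comparing against the motif itself."""
    L = len(seq)
    out = []
    for p in periods:
        pos = 0
        while pos + p <= L:
            motif = seq[pos : pos + p]
            if "N" in motif:
                pos += 1
                continue
            run_len = p
            while (
                pos + run_len < L
                and seq[pos + run_len] != "N"
                and seq[pos + run_len] == motif[run_len % p]
            ):
                run_len += 1
            n_units = run_len // p
            if n_units >= min_units and _primitive(motif):
                out.append((pos, pos + run_len, p, motif, n_units))
                pos += run_len
            else:
                pos += 1
    out.sort(key=lambda x: (x[0], x[2]))
    return out


def fisher_greater_by_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact P(X >= a) by summing hypergeometric terms over all tables
    with the observed margins."""
    n1, K, N = a + b, a + c, a + b + c + d
    denom = comb(N, K)
    total = Fraction(0)
    for x in range(max(0, K - (c + d)), min(n1, K) + 1):
        if x >= a:
            total += Fraction(comb(n1, x) * comb(c + d, K - x), denom)
    return total


def bh_step_up(pvalues):
    """Textbook BH step-up adjusted values, computed by hand from the
    definition: adj_(i) = min_{j>=i} m p_(j)/j capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out
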