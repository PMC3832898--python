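"""ORF calling: translation, longest-ORF selection, UTRs, length stats."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from transchar.orfs import (
    OrfCall,
    Transcript,
    find_longest_orf,
    orf_length_stats,
    translate,
    utr_intervals,
)

from conftest import random_dna
from oracles import brute_force_longest_orf


class TestTranslate:
    @pytest.mark.parametrize(
        "dna, offset, expected",
        [
            ("ATGAAATAG", 0, "MK*"),
            ("ATGANAGGG", 0, "MXG"),  # N-containing codon -> X
            ("CATGAA", 1, "M"),  # trailing partial codon dropped
            ("ATGNNNTAA", 0, "MX*"),
            ("atgaaa", 0, "MK"),  # case-insensitive
        ],
    )
    def test_examples(self, dna, offset, expected):
        assert translate(dna, offset) == expected

    def test_rejects_bad_offset_and_alphabet(self):
        with pytest.raises(ValueError):
            translate("ATG", 3)
        with pytest.raises(ValueError):
            translate("ATQ")


class TestFindLongestOrf:
    def test_minimum_length_boundary(self):
        t = Transcript("t", "ATG" + "AAA" * 19 + "TAA")
        o = find_longest_orf(t)
        assert (o.n_aa, o.n_x, o.start, o.end) == (20, 0, 0, 60)
        shorter = Transcript("s", "ATG" + "AAA" * 18 + "TAA")
        assert find_longest_orf(shorter) is None

    def test_no_start_codon(self):
        assert find_longest_orf(Transcript("t", "CCCCCC" * 20)) is None

    def test_x_runs_do_not_terminate_but_do_not_count(self):
        # 26 residues total but only one effective: below the threshold
        t = Transcript("t", "ATG" + "NNN" * 25 + "TAA")
        assert find_longest_orf(t) is None
        # same span passes when the threshold counts every residue
        assert find_longest_orf(t, count_x=True).n_aa == 26

    def test_orf_may_run_to_sequence_end(self):
        t = Transcript("t", "ATG" + "GCT" * 25)
        o = find_longest_orf(t)
        assert o is not None and not o.has_stop and o.end == len(t.seq)

    def test_reverse_strand_call_mirrors_coordinates(self):
        fwd = "ATG" + "GAA" * 30 + "TGA"
        pad5, pad3 = "CCCCC", "GGGGGGG"
        seq = pad5 + reverse_complement(fwd) + pad3
        o = find_longest_orf(Transcript("t", seq))
        assert o.strand == "-"
        # reading right-to-left: ATG at the high-coordinate end, the stop
        # codon (revcomp TGA = TCA) just after pad5
        assert o.start == len(pad5) + 3
        assert o.end == len(seq) - len(pad3)
        assert o.aa_seq == "M" + "E" * 30

    def test_brute_force_oracle_equivalence_sample(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            seq = random_dna(rng, int(rng.integers(100, 1500)), n_prob=0.01)
            t = Transcript("t", seq)
            got = find_longest_orf(t)
            want = brute_force_longest_orf(seq)
            if want is None:
                assert got is None
            else:
                assert (got.strand, got.start, got.end, got.aa_seq) == want

    def test_invariants_on_any_call(self):
        rng = np.random.default_rng(7)
        calls = 0
        while calls < 20:
            t = Transcript("t", random_dna(rng, 900, n_prob=0.02))
            o = find_longest_orf(t)
            if o is None:
                continue
            calls += 1
            assert o.end - o.start == 3 * o.n_aa
            assert o.effective_len == o.n_aa - o.n_x >= 20
            assert o.aa_seq.startswith("M")

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            seq = random_dna(rng, 700)
            t = Transcript("t", seq)
            o1 = find_longest_orf(t)
            o2 = find_longest_orf(Transcript("t", reverse_complement(seq)))
            if o1 is None:
                assert o2 is None
                continue
            L = len(seq)
            assert o2.aa_seq == o1.aa_seq
            assert (o2.start, o2.end) == (L - o1.end, L - o1.start)


class TestUtrIntervals:
    def test_orf_spanning_whole_transcript(self):
        seq = "ATG" + "AAA" * 30
        t = Transcript("t", seq)
        o = find_longest_orf(t)
        utr5, utr3 = utr_intervals(t, o)
        assert utr5 == (0, 0) and utr3 == (len(seq), len(seq))

    def test_forward_orf_with_stop(self):
        seq = "C" * 10 + "ATG" + "GGG" * 19 + "TAA" + "T" * 27
        t = Transcript("t", seq)
        o = find_longest_orf(t)
        assert (o.start, o.end) == (10, 70)
        utr5, utr3 = utr_intervals(t, o)
        assert utr5 == (0, 10) and utr3 == (73, 100)

    def test_reverse_orf_utr5_at_high_coordinates(self):
        fwd = "ATG" + "GAA" * 25 + "TAG"
        seq = "C" * 8 + reverse_complement(fwd) + "A" * 6
        t = Transcript("t", seq)
        o = find_longest_orf(t)
        assert o.strand == "-"
        utr5, utr3 = utr_intervals(t, o)
        assert utr5 == (o.end, len(seq))  # 5'UTR at the transcript's 3' end
        assert utr3 == (0, o.start - 3)

    def test_transcript_mismatch_rejected(self):
        t = Transcript("a", "ATG" + "AAA" * 20 + "TAA")
        o = find_longest_orf(t)
        with pytest.raises(ValueError):
            utr_intervals(Transcript("b", t.seq), o)


class TestOrfLengthStats:
    def _call(self, n_aa, n_x):
        aa = "M" + "X" * n_x + "K" * (n_aa - n_x - 1)
        return OrfCall("t", "+", 0, 0, 3 * n_aa, aa)

    def test_mean_with_and_without_x(self):
        stats = orf_length_stats([self._call(100, 20)])
        assert stats.mean == 100
        stats_x = orf_length_stats([self._call(100, 20)], exclude_x=True)
        assert stats_x.mean == 80

    def test_mean_of_two(self):
        assert orf_length_stats([self._call(20, 0), self._call(40, 0)]).mean == 30

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            orf_length_stats([])
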