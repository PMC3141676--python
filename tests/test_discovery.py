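"""Candidate selection, window extraction, hairpin screening, the
shuffle test, homogeneity and the accept/reject rule."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnakit.discovery import (MiRNAReport, Window, decide, dinucleotide_shuffle, extract_window,
                               five_prime_homogeneity, hairpin_check, hairpin_search, randfold_p,
                               report_summary, select_candidates)
from srnakit.mapping import GenomeHit
from srnakit.reads import Tag
from srnakit.sequences import random_dna, revcomp


class TestSelectCandidates:
    def _tag(self, reads, n_hits):
        t = Tag("A" * 20, {"L": reads})
        hits = {t.sequence: [GenomeHit("c", i * 50, i * 50 + 20, "+") for i in range(n_hits)]}
        return t, hits

    @pytest.mark.parametrize("reads,n_hits,kept", [
        (2, 20, True),   # boundary of both thresholds
        (1, 1, False),   # needs more than one read
        (50, 21, False), # too many genome hits
        (2, 0, False),   # unmapped
        (2, 1, True),
    ])
    def test_read_and_hit_thresholds(self, reads, n_hits, kept):
        t, hits = self._tag(reads, n_hits)
        assert (select_candidates([t], hits) == [t]) is kept


class TestExtractWindow:
    GENOME = {"chr": random_dna(np.random.default_rng(0), 10_000)}

    def test_interior_hit_gets_symmetric_flanks(self):
        w = extract_window(GenomeHit("chr", 500, 521, "+"), self.GENOME)
        assert len(w.seq) == 621
        assert w.mature == (300, 321)
        assert w.seq[300:321] == self.GENOME["chr"][500:521]

    def test_left_clipped_window(self):
        w = extract_window(GenomeHit("chr", 50, 71, "+"), self.GENOME)
        assert len(w.seq) == 371
        assert w.mature == (50, 71)

    def test_minus_strand_window_is_reverse_complement(self):
        hit = GenomeHit("chr", 500, 521, "-")
        w = extract_window(hit, self.GENOME)
        assert w.seq == revcomp(self.GENOME["chr"][200:821])
        a, b = w.mature
        assert w.seq[a:b] == revcomp(self.GENOME["chr"][500:521])
        assert w.to_genomic(w.mature) == (500, 521)


def _planted_window(seed=0, stem=22, mature_len=21, loop="CTTAAAGC"):
    rng = np.random.default_rng(seed)
    arm = random_dna(rng, stem)
    hairpin = arm + loop + revcomp(arm)
    left, right = random_dna(rng, 60), random_dna(rng, 60)
    seq = left + hairpin + right
    return Window("chr", "+", 0, len(seq), seq, (60, 60 + mature_len))


class TestHairpinCheck:
    def test_planted_hairpin_is_accepted(self):
        cand = hairpin_check(_planted_window())
        assert not isinstance(cand, str)
        assert cand.paired_bases >= 16
        assert cand.bulges == 0
        assert cand.precursor_mfe <= -18

    def test_mature_in_terminal_loop_is_rejected(self):
        w = _planted_window(stem=25, loop="CTTAAAGCAA")
        # straddle the terminal loop: last arm bases + loop + first star bases
        loop_start = 60 + 25
        bad = Window(w.chrom, w.strand, w.gstart, w.gend, w.seq, (loop_start - 7, loop_start + 13))
        reasons = hairpin_search(bad)
        assert isinstance(reasons, list)
        assert "loop-spanning" in reasons

    def test_unstructured_window_is_rejected_for_energy(self):
        # alternating A/C cannot pair at all under WC+GU rules
        seq = "AC" * 80
        w = Window("chr", "+", 0, 160, seq, (60, 81))
        assert hairpin_check(w) == "energy"

    def test_mature_length_bounds(self):
        w = _planted_window()
        short = Window(w.chrom, w.strand, w.gstart, w.gend, w.seq, (60, 60 + 17))
        long_ = Window(w.chrom, w.strand, w.gstart, w.gend, w.seq, (60, 60 + 26))
        assert hairpin_check(short) == "mature-length"
        assert hairpin_check(long_) == "mature-length"

    def test_symmetric_mismatches_are_counted_not_bulges(self):
        rng = np.random.default_rng(12)
        arm = random_dna(rng, 22)
        star = list(revcomp(arm))
        star[10] = {"A": "C", "C": "A", "G": "A", "T": "C"}[arm[11]]  # symmetric mismatch
        seq = random_dna(rng, 60) + arm + "CTTAAAGC" + "".join(star) + random_dna(rng, 60)
        cand = hairpin_search(Window("chr", "+", 0, len(seq), seq, (60, 81)))
        assert not isinstance(cand, list)
        assert cand.bulges == 0
        assert cand.mismatches >= 1


class TestDinucleotideShuffle:
    @staticmethod
    def dinucs(s):
        return Counter(s[i:i + 2] for i in range(len(s) - 1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 9999), st.integers(10, 80))
    def test_preserves_dinucleotides_and_endpoints(self, seed, length):
        rng = np.random.default_rng(seed)
        s = random_dna(rng, length)
        shuffled = dinucleotide_shuffle(s, rng)
        assert self.dinucs(shuffled) == self.dinucs(s)
        assert Counter(shuffled) == Counter(s)
        assert shuffled[0] == s[0] and shuffled[-1] == s[-1]

    def test_acacac_only_permutes_within_its_walk_set(self):
        rng = np.random.default_rng(0)
        results = {dinucleotide_shuffle("ACACAC", rng) for _ in range(50)}
        assert results == {"ACACAC"}  # the only Eulerian arrangement

    def test_homopolymer_is_unchanged(self):
        rng = np.random.default_rng(0)
        assert dinucleotide_shuffle("AAAAAAAA", rng) == "AAAAAAAA"

    def test_shuffles_actually_vary(self):
        rng = np.random.default_rng(1)
        s = random_dna(rng, 60)
        assert len({dinucleotide_shuffle(s, rng) for _ in range(20)}) > 5


class TestRandfold:
    def test_homopolymer_p_is_one(self):
        res = randfold_p("A" * 40, 19, np.random.default_rng(0))
        assert res.p_value == 1.0

    def test_perfect_stem_gets_minimal_p(self):
        rng = np.random.default_rng(2)
        arm = random_dna(rng, 30)
        precursor = arm + "CTTAAAGC" + revcomp(arm)
        res = randfold_p(precursor, 199, np.random.default_rng(3))
        assert res.p_value == pytest.approx(1 / 200)

    def test_zero_shuffles_is_degenerate_with_warning(self):
        with pytest.warns(UserWarning):
            res = randfold_p("ACGT" * 10, 0)
        assert res.p_value == 1.0

    def test_fixed_seed_reproduces(self):
        s = random_dna(np.random.default_rng(5), 50)
        a = randfold_p(s, 49, np.random.default_rng(7)).p_value
        b = randfold_p(s, 49, np.random.default_rng(7)).p_value
        assert a == b


class TestFivePrimeHomogeneity:
    MATURE = GenomeHit("chr", 500, 521, "+")

    def test_hand_counted_fraction(self):
        reads = [
            (GenomeHit("chr", 500, 521, "+"), 2),  # exact 5'
            (GenomeHit("chr", 500, 522, "+"), 1),  # exact 5', different 3'
            (GenomeHit("chr", 501, 522, "+"), 1),  # shifted by +1
        ]
        num, den = five_prime_homogeneity(reads, self.MATURE, (450, 600))
        assert (num, den) == (3, 4)

    def test_all_reads_identical_gives_one(self):
        reads = [(GenomeHit("chr", 500, 521, "+"), 7)]
        num, den = five_prime_homogeneity(reads, self.MATURE, (450, 600))
        assert num == den == 7

    def test_minus_strand_uses_right_end(self):
        mature = GenomeHit("chr", 500, 521, "-")
        reads = [(GenomeHit("chr", 499, 521, "-"), 3), (GenomeHit("chr", 499, 520, "-"), 2)]
        num, den = five_prime_homogeneity(reads, mature, (450, 600))
        assert (num, den) == (3, 5)

    def test_no_reads_is_zero_over_zero(self):
        assert five_prime_homogeneity([], self.MATURE, (450, 600)) == (0, 0)


class TestDecide:
    @pytest.mark.parametrize("p,num,den,expected", [
        (0.019, 6, 9, True),    # low p, homogeneity 0.667 > 0.5
        (0.801, 69, 71, True),  # high p, homogeneity 0.972 >= 0.75
        (0.5, 1, 2, False),     # high p needs >= 0.75
        (0.05, 5, 9, True),     # boundary p counts as low
        (0.04, 1, 2, False),    # low p needs strictly > 0.5
    ])
    def test_paired_rule(self, p, num, den, expected):
        accept, _, _ = decide(p, {"PT1": (num, den)})
        assert accept is expected

    def test_best_library_is_used(self):
        accept, _, lib = decide(0.5, {"PT1": (1, 10), "PT2": (9, 10), "PT3": (0, 0)})
        assert accept and lib == "PT2"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.001, 1.0), st.integers(0, 20), st.integers(1, 20))
    def test_monotone_in_homogeneity(self, p, num, den):
        num = min(num, den)
        low, _, _ = decide(p, {"L": (num, den)})
        high, _, _ = decide(p, {"L": (den, den)})
        assert high or not low  # raising homogeneity never flips accept -> reject


class TestReportSummary:
    def _report(self, name, length, mfe):
        return MiRNAReport(name, "chr:1:100:+", mfe, length, 0.1, {"PT1": (0, 0)}, 0, 0)

    def test_floor_mean_length_convention(self):
        lengths = [278, 321, 101, 160, 222, 141, 119, 232, 267, 360, 261, 320, 281]
        reports = [self._report(f"m{i}", L, -50.0) for i, L in enumerate(lengths)]
        summary = report_summary(reports)
        assert summary["len_mean_floor"] == 235  # 3063/13 = 235.6 floors to 235
        assert summary["len_max"] == 360

    def test_zero_over_zero_cell_rendering(self):
        r = self._report("m", 100, -30.0)
        assert r.homogeneity_cell("PT2") == "0/0"

    def test_empty_accept_set(self):
        assert report_summary([]) == {}
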