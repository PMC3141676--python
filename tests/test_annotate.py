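"""Annotation evidence gathering, the priority rule, siRNA duplexes,
phasing and repeat overlap."""

import itertools

import numpy as np
import pytest

from srnakit.annotate import (GeneIndex, build_ncrna_matcher, classify, classify_gene_overlap,
                              find_sirna_pairs, is_sirna_duplex, match_known_mirna, match_ncrna,
                              phasing_statistic, repeat_overlap, summarize_categories)
from srnakit.io import GeneModel, RefSeq
from srnakit.mapping import GenomeHit
from srnakit.reads import Tag
from srnakit.sequences import random_dna, revcomp


def ungapped_oracle(tag: str, ref: str) -> bool:
    """Brute-force check for any >=16-nt >=90%-identity ungapped local
    alignment between tag (either orientation) and ref."""
    for q in (tag, revcomp(tag)):
        for diag in range(-len(q) + 1, len(ref)):
            lo = max(0, -diag)
            hi = min(len(q), len(ref) - diag)
            if hi - lo < 16:
                continue
            m = [q[k] == ref[k + diag] for k in range(lo, hi)]
            for w in range(16, len(m) + 1):
                for s in range(0, len(m) - w + 1):
                    if sum(m[s:s + w]) / w >= 0.90:
                        return True
    return False


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(4)
    return [
        RefSeq("rRNA_X", random_dna(rng, 120), "rRNA", "genbank"),
        RefSeq("tRNA_X", random_dna(rng, 75), "tRNA", "rfam"),
        RefSeq("snRNA_X", random_dna(rng, 100), "snRNA", "genbank"),
    ]


class TestMatchNcrna:
    def test_exact_substring_hits_its_class(self, refs):
        matcher = build_ncrna_matcher(refs)
        tag = refs[0].sequence[30:51]
        hit = match_ncrna(tag, matcher)
        assert hit is not None and hit.rclass == "rRNA" and hit.identity == 1.0

    def test_genbank_outranks_rfam_on_equal_evidence(self):
        shared = random_dna(np.random.default_rng(9), 60)
        pair = [RefSeq("rfam_copy", shared, "tRNA", "rfam"),
                RefSeq("genbank_copy", shared, "rRNA", "genbank")]
        hit = match_ncrna(shared[10:31], build_ncrna_matcher(pair))
        assert hit.source == "genbank" and hit.rclass == "rRNA"

    def test_agrees_with_exhaustive_alignment_oracle(self, refs):
        rng = np.random.default_rng(21)
        matcher = build_ncrna_matcher(refs)
        for trial in range(120):
            kind = rng.integers(3)
            if kind == 0:
                tag = random_dna(rng, int(rng.integers(18, 29)))
            elif kind == 1:  # exact fragment
                ref = refs[rng.integers(len(refs))]
                s = int(rng.integers(0, len(ref.sequence) - 24))
                tag = ref.sequence[s:s + 24]
            else:  # fragment with two substitutions
                ref = refs[rng.integers(len(refs))]
                s = int(rng.integers(0, len(ref.sequence) - 24))
                tag = list(ref.sequence[s:s + 24])
                for pos in rng.choice(24, size=2, replace=False):
                    tag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[pos]]
                tag = "".join(tag)
            expected = any(ungapped_oracle(tag, r.sequence) for r in refs)
            assert (match_ncrna(tag, matcher) is not None) == expected, tag


class TestMatchKnownMirna:
    MATURE = [RefSeq("syn-miR900", "ACGGATTACGCTAGGCTTACG", "miRNA", "mirbase")]

    def test_identical_tag_hits_with_zero_mismatches(self):
        hit = match_known_mirna("ACGGATTACGCTAGGCTTACG", self.MATURE)
        assert hit is not None and hit.mismatches == 0

    def test_two_mismatches_still_hit(self):
        tag = "ACGGATTACGCTAGGCTTACG"
        mutated = "TA" + tag[2:]
        hit = match_known_mirna(mutated, self.MATURE)
        assert hit is not None and hit.mismatches <= 2

    def test_three_mismatches_in_twenty_is_no_hit(self):
        tag = list("ACGGATTACGCTAGGCTTACG")
        for pos in (0, 5, 11):
            tag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[pos]]
        assert match_known_mirna("".join(tag), self.MATURE) is None

    def test_length_difference_above_two_is_no_hit(self):
        assert match_known_mirna("ACGGATTACGCTAGG", self.MATURE) is None


class TestGeneOverlap:
    GENES = [GeneModel("g1", "chr1", "+", [(100, 300), (420, 600)])]

    def test_hit_inside_exon_same_strand(self):
        gi = GeneIndex(self.GENES)
        assert classify_gene_overlap([GenomeHit("chr1", 150, 172, "+")], gi) == "exon_sense"

    def test_hit_inside_intron_opposite_strand(self):
        gi = GeneIndex(self.GENES)
        assert classify_gene_overlap([GenomeHit("chr1", 350, 372, "-")], gi) == "intron_antisense"

    def test_boundary_straddling_hit_contributes_nothing(self):
        gi = GeneIndex(self.GENES)
        assert classify_gene_overlap([GenomeHit("chr1", 290, 312, "+")], gi) is None

    def test_exon_outranks_intron_across_hits(self):
        gi = GeneIndex(self.GENES)
        hits = [GenomeHit("chr1", 320, 342, "+"), GenomeHit("chr1", 150, 172, "+")]
        assert classify_gene_overlap(hits, gi) == "exon_sense"


class TestSirnaPairs:
    def test_constructed_duplex_is_detected(self):
        rng = np.random.default_rng(6)
        t = random_dna(rng, 23)  # dsRNA window of L+2 = 23
        a = t[2:]
        b = revcomp(t[:21])
        pairs = find_sirna_pairs([Tag(a, {"L": 1}), Tag(b, {"L": 1})])
        assert len(pairs) == 1
        assert {pairs[0].tag_a, pairs[0].tag_b} == {a, b}

    def test_blunt_reverse_complement_is_not_a_pair(self):
        a = random_dna(np.random.default_rng(7), 21)
        assert find_sirna_pairs([Tag(a, {"L": 1}), Tag(revcomp(a), {"L": 1})]) == []

    def test_random_tags_yield_no_spurious_pairs(self):
        rng = np.random.default_rng(8)
        tags = [Tag(random_dna(rng, int(rng.integers(18, 25))), {"L": 1}) for _ in range(1000)]
        for p in find_sirna_pairs(tags):
            assert is_sirna_duplex(p.tag_a, p.tag_b)

    def test_pair_detection_is_symmetric(self, dataset):
        pairs = find_sirna_pairs(dataset.tags)
        keys = [tuple(sorted((p.tag_a, p.tag_b))) for p in pairs]
        assert len(keys) == len(set(keys))  # each unordered pair reported once
        assert len(pairs) >= dataset.config.n_sirna_pairs


class TestClassifyPriority:
    def test_ncrna_beats_exon(self):
        from srnakit.annotate import NcrnaHit

        call = classify(Tag("A" * 20, {"L": 1}),
                        ncrna_hit=NcrnaHit("rRNA_X", "rRNA", "genbank", 20, 1.0),
                        gene_category="exon_sense")
        assert call.category == "rRNA"

    def test_known_mirna_beats_intron(self):
        from srnakit.annotate import MirnaHit

        call = classify(Tag("A" * 20, {"L": 1}),
                        mirna_hit=MirnaHit("syn-miR1", 0, 1.0, 20),
                        gene_category="intron_sense")
        assert call.category == "known_miRNA"

    def test_no_evidence_is_non_annotated(self):
        call = classify(Tag("A" * 20, {"L": 1}))
        assert call.category == "non_annotated"
        assert call.evidence is None

    def test_priority_ignores_evidence_arrival_order(self):
        from srnakit.annotate import MirnaHit, NcrnaHit

        evidence = dict(
            ncrna_hit=NcrnaHit("tRNA_X", "tRNA", "rfam", 18, 0.95),
            mirna_hit=MirnaHit("syn-miR1", 1, 0.95, 20),
            gene_category="exon_antisense",
            in_sirna_pair=True,
        )
        cats = set()
        for order in itertools.permutations(evidence):
            kwargs = {k: evidence[k] for k in order}
            cats.add(classify(Tag("A" * 20, {"L": 1}), **kwargs).category)
        assert cats == {"tRNA"}


def test_category_counts_partition_each_library(dataset):
    libs = list(dataset.config.library_ids)
    table = summarize_categories(dataset.calls, dataset.tags, libs)
    body = table[table["category"] != "total"]
    totals = table[table["category"] == "total"].iloc[0]
    for lib in libs:
        assert body[f"{lib}_unique"].sum() == totals[f"{lib}_unique"]
        assert body[f"{lib}_total"].sum() == totals[f"{lib}_total"]


class TestPhasing:
    def test_perfectly_phased_starts_score_one(self):
        starts = [21 * k for k in range(10)]
        score, p = phasing_statistic(starts, locus_len=210, n_permutations=200)
        assert score == 1.0
        assert p < 0.05

    def test_uniform_starts_are_not_phased(self):
        rng = np.random.default_rng(10)
        starts = list(rng.integers(0, 2100, size=210))
        score, p = phasing_statistic(starts, locus_len=2100, n_permutations=500,
                                     rng=np.random.default_rng(0))
        assert p > 0.05
        assert score < 0.15

    def test_ninety_percent_phased_is_significant_at_n_100(self):
        rng = np.random.default_rng(11)
        starts = [21 * int(rng.integers(0, 47)) for _ in range(90)]
        starts += [int(rng.integers(0, 1000)) for _ in range(10)]
        _, p = phasing_statistic(starts, locus_len=1000, n_permutations=999,
                                 rng=np.random.default_rng(1))
        assert p < 0.01

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            phasing_statistic([])


class TestRepeatOverlap:
    REPEATS = [("chr1", 1000, 1500, "rep1"), ("chr1", 3000, 3400, "rep2")]

    def test_tag_counted_once_despite_multiple_repeat_hits(self):
        tag = Tag("A" * 20, {"L": 1})
        hits = [GenomeHit("chr1", 1100, 1120, "+"), GenomeHit("chr1", 3100, 3120, "+"),
                GenomeHit("chr1", 1200, 1220, "-")]
        assert repeat_overlap([(tag, hits)], self.REPEATS) == 1

    def test_boundary_overlap_is_not_containment(self):
        tag = Tag("A" * 20, {"L": 1})
        assert repeat_overlap([(tag, [GenomeHit("chr1", 990, 1010, "+")])], self.REPEATS) == 0

    def test_empty_repeat_set(self):
        tag = Tag("A" * 20, {"L": 1})
        assert repeat_overlap([(tag, [GenomeHit("chr1", 1100, 1120, "+")])], []) == 0
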