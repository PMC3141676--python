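"""Exact-match, all-hits, both-strand tag placement plus per-chromosome
strand profiles, hot-spot extraction and locus-vs-locus alignment.

The index is a hashed k-mer seed table (k = 10) over the forward strand;
a query's first k-mer nominates candidate offsets which are verified by
string comparison, giving all zero-mismatch occurrences in time
proportional to query length plus hits. Minus-strand placements are
found by looking up the reverse complement: a hit (chrom, -, s, e) means
the tag equals revcomp(genome[s:e]).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .sequences import revcomp, validate_dna

SEED_K = 10


@dataclass(frozen=True, order=True)
class GenomeHit:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str

    def render(self) -> str:
        """1-based inclusive report rendering, e.g. ``chr_1:1604545:1604822:-``."""
        return f"{self.chrom}:{self.start + 1}:{self.end}:{self.strand}"


class ExactIndex:
    """Seed-and-verify exact index over a named sequence set."""

    def __init__(self, genome: dict[str, str], k: int = SEED_K):
        self.k = k
        self.genome = {name: validate_dna(seq) for name, seq in genome.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i:i + k], []).append((name, i))

    def lookup(self, query: str) -> list[tuple[str, int]]:
        """All forward-strand occurrences of ``query`` (length >= k)."""
        q = query.upper()
        if len(q) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        out = []
        for name, i in self._seeds.get(q[: self.k], ()):
            if self.genome[name][i:i + len(q)] == q:
                out.append((name, i))
        return out


def build_index(genome: dict[str, str], k: int = SEED_K) -> ExactIndex:
    return ExactIndex(genome, k)


def map_tag(tag: str, index: ExactIndex) -> list[GenomeHit]:
    """All exact placements of a tag on both strands, sorted by
    (chrom, start, strand). Tags containing N are rejected."""
    seq = validate_dna(tag)  # raises on N: the index is defined over ACGT
    hits = [GenomeHit(name, i, i + len(seq), "+") for name, i in index.lookup(seq)]
    rc = revcomp(seq)
    for name, i in index.lookup(rc):
        hits.append(GenomeHit(name, i, i + len(seq), "-"))
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def map_all(tags, index: ExactIndex) -> dict[str, list[GenomeHit]]:
    """Map a collection of Tag objects; returns sequence -> hit list."""
    return {t.sequence: map_tag(t.sequence, index) for t in tags}


def strand_profile(
    tags_with_hits: list[tuple[object, list[GenomeHit]]],
    library: str | None = None,
    weighting: str = "all",
) -> dict[tuple[str, str], float]:
    """Redundant read counts per (chromosome, strand).

    ``weighting="all"`` gives every hit the tag's full redundant count
    (every reported hit counts, matching an all-hits mapper's output);
    ``"fractional"`` spreads the count evenly across hits."""
    if weighting not in ("all", "fractional"):
        raise ValueError("weighting must be 'all' or 'fractional'")
    profile: dict[tuple[str, str], float] = {}
    for tag, hits in tags_with_hits:
        if not hits:
            continue
        count = tag.count(library) if library is not None else tag.total
        if count == 0:
            continue
        w = count if weighting == "all" else count / len(hits)
        for h in hits:
            key = (h.chrom, h.strand)
            profile[key] = profile.get(key, 0.0) + w
    return profile


def find_hotspots(
    tags_with_hits: list[tuple[object, list[GenomeHit]]],
    window_len: int = 1000,
    step: int = 500,
    min_reads: float | None = None,
    library: str | None = None,
    total_fraction: float = 0.01,
) -> list[tuple[str, str, int, int, float]]:
    """Sliding-window read clusters per chromosome strand.

    Windows of ``window_len`` advanced by ``step`` whose redundant read
    count (all-hits weighting, 5'-end binning) reaches ``min_reads`` are
    merged into maximal runs; merged intervals are re-scored and returned
    sorted by read count descending, then by coordinate. ``min_reads``
    defaults to ``total_fraction`` of the mapped library total."""
    starts: dict[tuple[str, str], list[tuple[int, int]]] = {}
    total = 0.0
    for tag, hits in tags_with_hits:
        count = tag.count(library) if library is not None else tag.total
        if count == 0 or not hits:
            continue
        total += count
        for h in hits:
            five_prime = h.start if h.strand == "+" else h.end - 1
            starts.setdefault((h.chrom, h.strand), []).append((five_prime, count))
    if min_reads is None:
        min_reads = total_fraction * total
    results = []
    for (chrom, strand), positions in starts.items():
        positions.sort()
        if not positions:
            continue
        limit = positions[-1][0] + 1
        hot: list[tuple[int, int]] = []
        for wstart in range(0, limit, step):
            wend = wstart + window_len
            reads = sum(c for p, c in positions if wstart <= p < wend)
            if reads >= min_reads and reads > 0:
                hot.append((wstart, wend))
        # merge overlapping/adjacent qualifying windows
        merged: list[list[int]] = []
        for s, e in hot:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            reads = sum(c for p, c in positions if s <= p < e)
            results.append((chrom, strand, s, e, reads))
    return sorted(results, key=lambda r: (-r[4], r[0], r[1], r[2]))


_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-2, extend_gap_score=-2
)


def align_loci(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and gap fraction of the best local alignment of two loci.

    Identity is the fraction of the shorter locus whose bases align
    identically: two copies of one sequence give 1.0, while unrelated
    loci give a value near zero even though their best (short) local
    alignment has high per-column identity — the measure asks whether the
    loci are homologous over their length, which is the question a
    hot-spot comparison poses. The gap fraction is gapped columns over
    all columns of the aligned region."""
    aln = _aligner.align(seq_a.upper(), seq_b.upper())[0]
    matches = aligned = 0
    for (a_s, a_e), (b_s, b_e) in zip(*aln.aligned):
        seg_a = seq_a.upper()[a_s:a_e]
        seg_b = seq_b.upper()[b_s:b_e]
        aligned += len(seg_a)
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
    span_a = aln.aligned[0][-1][1] - aln.aligned[0][0][0] if len(aln.aligned[0]) else 0
    span_b = aln.aligned[1][-1][1] - aln.aligned[1][0][0] if len(aln.aligned[1]) else 0
    columns = max(span_a, span_b)
    gaps = columns - aligned if columns > aligned else 0
    identity = matches / min(len(seq_a), len(seq_b)) if seq_a and seq_b else 0.0
    gap_fraction = gaps / columns if columns else 0.0
    return identity, gap_fraction
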