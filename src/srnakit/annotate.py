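"""Tag annotation: ncRNA/known-miRNA homology, gene overlap, siRNA
duplex detection, the priority classification rule, category summaries,
phasing statistics and repeat overlap.

Every tag receives exactly one category through the priority chain

    rRNA/tRNA/snRNA/snoRNA (GenBank > Rfam) > known_miRNA > exon >
    intron > siRNA > non_annotated

so the per-library category counts partition the tag set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, RefSeq
from .mapping import GenomeHit
from .reads import Tag, percent
from .sequences import revcomp

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
CATEGORIES = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "known_miRNA",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
    "siRNA", "non_annotated",
)
_SOURCE_RANK = {"genbank": 0, "rfam": 1}

MIN_UNGAPPED_LEN = 16
MIN_UNGAPPED_IDENTITY = 0.90
_SEED_LEN = 8  # a >=16-nt window at >=90% identity contains an exact >=8-mer


@dataclass(frozen=True)
class NcrnaHit:
    ref: str
    rclass: str
    source: str
    length: int
    identity: float


@dataclass(frozen=True)
class MirnaHit:
    ref: str
    mismatches: int
    identity: float
    overlap: int


@dataclass
class AnnotationCall:
    tag: str
    category: str
    evidence: object = None


@dataclass(frozen=True)
class SirnaPair:
    """Two perfectly complementary tags with 2-nt 3' overhangs."""

    tag_a: str
    tag_b: str
    offset: int = 2  # each 3' end protrudes by exactly this many nt


def is_sirna_duplex(tag_a: str, tag_b: str, overhang: int = 2) -> bool:
    """True iff the two tags form a perfect duplex with ``overhang``-nt 3'
    overhangs on both strands: equal lengths L, and the first L-2 nt of
    one strand are the reverse complement of the first L-2 nt of the
    other (each strand's final 2 nt hang off the duplex 3' end)."""
    if len(tag_a) != len(tag_b) or len(tag_a) <= overhang:
        return False
    core = len(tag_a) - overhang
    return tag_b[:core] == revcomp(tag_a[:core])


class _UngappedMatcher:
    """Seed (8-mer) + diagonal extension search for ungapped local matches
    of >= MIN_UNGAPPED_LEN nt at >= MIN_UNGAPPED_IDENTITY identity."""

    def __init__(self, refs: list[RefSeq]):
        self.refs = refs
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for ridx, ref in enumerate(refs):
            seq = ref.sequence
            for i in range(len(seq) - _SEED_LEN + 1):
                self._seeds.setdefault(seq[i:i + _SEED_LEN], []).append((ridx, i))

    @staticmethod
    def _best_window(matches: np.ndarray) -> tuple[int, float] | None:
        """Longest window with >= 90% identity and length >= 16 on one
        diagonal; returns (length, identity) preferring higher identity at
        equal length."""
        n = len(matches)
        best = None
        cum = np.concatenate([[0], np.cumsum(matches)])
        for w in range(n, MIN_UNGAPPED_LEN - 1, -1):
            for s in range(0, n - w + 1):
                ident = (cum[s + w] - cum[s]) / w
                if ident >= MIN_UNGAPPED_IDENTITY:
                    cand = (w, float(ident))
                    if best is None or cand > best:
                        best = cand
            if best is not None:
                break  # longest qualifying window found
        return best

    def search(self, query: str) -> list[tuple[int, int, float]]:
        """Return (ref index, matched length, identity) candidates."""
        out = {}
        for orient_query in (query, revcomp(query)):
            diagonals = set()
            for qpos in range(len(orient_query) - _SEED_LEN + 1):
                for ridx, rpos in self._seeds.get(orient_query[qpos:qpos + _SEED_LEN], ()):
                    diagonals.add((ridx, rpos - qpos))
            for ridx, diag in diagonals:
                ref = self.refs[ridx].sequence
                q_lo = max(0, -diag)
                q_hi = min(len(orient_query), len(ref) - diag)
                if q_hi - q_lo < MIN_UNGAPPED_LEN:
                    continue
                matches = np.fromiter(
                    (orient_query[q] == ref[q + diag] for q in range(q_lo, q_hi)),
                    dtype=bool,
                )
                hit = self._best_window(matches)
                if hit is not None:
                    prev = out.get(ridx)
                    if prev is None or hit > prev:
                        out[ridx] = hit
        return [(ridx, length, ident) for ridx, (length, ident) in out.items()]


def build_ncrna_matcher(refs: list[RefSeq]) -> _UngappedMatcher:
    return _UngappedMatcher([r for r in refs if r.rclass in NCRNA_CLASSES])


def match_ncrna(tag: str, matcher: _UngappedMatcher) -> NcrnaHit | None:
    """Best ncRNA hit under the deterministic ungapped criterion; ties are
    broken by source priority (GenBank > Rfam), then identity."""
    hits = []
    for ridx, length, ident in matcher.search(tag):
        ref = matcher.refs[ridx]
        hits.append(NcrnaHit(ref.name, ref.rclass, ref.source, length, ident))
    if not hits:
        return None
    return min(
        hits,
        key=lambda h: (_SOURCE_RANK.get(h.source, 9), -h.identity, -h.length, h.ref),
    )


def match_known_mirna(tag: str, mature_refs: list[RefSeq], max_len_diff: int = 2) -> MirnaHit | None:
    """Full-length gapless comparison against each mature miRNA, sliding to
    absorb a length difference of up to 2 nt; a hit needs <= 2 mismatches
    or >= 90% identity over the overlap."""
    best: MirnaHit | None = None
    for ref in mature_refs:
        a, b = tag.upper(), ref.sequence.upper()
        if abs(len(a) - len(b)) > max_len_diff:
            continue
        short, long_ = (a, b) if len(a) <= len(b) else (b, a)
        for off in range(len(long_) - len(short) + 1):
            mm = sum(1 for x, y in zip(short, long_[off:off + len(short)]) if x != y)
            ident = (len(short) - mm) / len(short)
            if mm <= 2 or ident >= 0.90:
                cand = MirnaHit(ref.name, mm, ident, len(short))
                if best is None or (cand.mismatches, -cand.identity) < (best.mismatches, -best.identity):
                    best = cand
    return best


class GeneIndex:
    """Interval lookup of exons and introns with transcript strand."""

    def __init__(self, genes: list[GeneModel]):
        self.exons: dict[str, IntervalTree] = {}
        self.introns: dict[str, IntervalTree] = {}
        for g in genes:
            for s, e in g.exons:
                self.exons.setdefault(g.chrom, IntervalTree()).addi(s, e, (g.gene_id, g.strand))
            for s, e in g.introns():
                self.introns.setdefault(g.chrom, IntervalTree()).addi(s, e, (g.gene_id, g.strand))

    @staticmethod
    def _contained(tree: IntervalTree | None, hit: GenomeHit):
        if tree is None:
            return []
        return [iv for iv in tree.overlap(hit.start, hit.end)
                if iv.begin <= hit.start and hit.end <= iv.end]


def classify_gene_overlap(hits: list[GenomeHit], gene_index: GeneIndex) -> str | None:
    """exon/intron x sense/antisense by full containment of a hit.

    A hit must lie entirely inside the exon or intron ("perfect overlap");
    boundary-straddling hits contribute nothing. Exon evidence outranks
    intron evidence, sense outranks antisense."""
    found = set()
    for hit in hits:
        for iv in GeneIndex._contained(gene_index.exons.get(hit.chrom), hit):
            found.add("exon_sense" if hit.strand == iv.data[1] else "exon_antisense")
        for iv in GeneIndex._contained(gene_index.introns.get(hit.chrom), hit):
            found.add("intron_sense" if hit.strand == iv.data[1] else "intron_antisense")
    for cat in ("exon_sense", "exon_antisense", "intron_sense", "intron_antisense"):
        if cat in found:
            return cat
    return None


def find_sirna_pairs(tags: list[Tag], overhang: int = 2) -> list[SirnaPair]:
    """All unordered tag pairs forming perfect duplexes with 2-nt 3'
    overhangs. Self-complementary tags do not pair with themselves."""
    by_core: dict[tuple[int, str], list[str]] = {}
    for t in tags:
        L = len(t.sequence)
        if L > overhang:
            by_core.setdefault((L, t.sequence[: L - overhang]), []).append(t.sequence)
    pairs = []
    seen = set()
    for t in tags:
        L = len(t.sequence)
        if L <= overhang:
            continue
        want = revcomp(t.sequence[: L - overhang])
        for other in by_core.get((L, want), ()):
            if other == t.sequence:
                continue  # self-pair
            key = tuple(sorted((t.sequence, other)))
            if key not in seen:
                seen.add(key)
                pairs.append(SirnaPair(key[0], key[1], overhang))
    return sorted(pairs, key=lambda p: (p.tag_a, p.tag_b))


def classify(
    tag: Tag,
    ncrna_hit: NcrnaHit | None = None,
    mirna_hit: MirnaHit | None = None,
    gene_category: str | None = None,
    in_sirna_pair: bool = False,
) -> AnnotationCall:
    """Apply the priority chain to the collected evidence for one tag."""
    if ncrna_hit is not None:
        return AnnotationCall(tag.sequence, ncrna_hit.rclass, ncrna_hit)
    if mirna_hit is not None:
        return AnnotationCall(tag.sequence, "known_miRNA", mirna_hit)
    if gene_category is not None:
        return AnnotationCall(tag.sequence, gene_category, gene_category)
    if in_sirna_pair:
        return AnnotationCall(tag.sequence, "siRNA", "duplex_partner")
    return AnnotationCall(tag.sequence, "non_annotated")


def annotate_tags(
    tags: list[Tag],
    ncrna_refs: list[RefSeq],
    mature_refs: list[RefSeq],
    genes: list[GeneModel],
    hits_by_tag: dict[str, list[GenomeHit]],
) -> dict[str, AnnotationCall]:
    """Run the full evidence-gathering + priority classification pass."""
    matcher = build_ncrna_matcher(ncrna_refs)
    gene_index = GeneIndex(genes)
    paired = set()
    for p in find_sirna_pairs(tags):
        paired.add(p.tag_a)
        paired.add(p.tag_b)
    calls = {}
    for t in tags:
        calls[t.sequence] = classify(
            t,
            ncrna_hit=match_ncrna(t.sequence, matcher),
            mirna_hit=match_known_mirna(t.sequence, mature_refs),
            gene_category=classify_gene_overlap(hits_by_tag.get(t.sequence, []), gene_index),
            in_sirna_pair=t.sequence in paired,
        )
    return calls


def summarize_categories(
    calls: dict[str, AnnotationCall], tags: list[Tag], libraries: list[str]
) -> pd.DataFrame:
    """Category x library matrix of unique/total counts with two-decimal
    percentages; categories partition the tags, so unique columns sum to
    the library's unique tag count."""
    by_seq = {t.sequence: t for t in tags}
    rows = []
    lib_unique = {lib: sum(1 for t in tags if t.count(lib) > 0) for lib in libraries}
    lib_total = {lib: sum(t.count(lib) for t in tags) for lib in libraries}
    for cat in CATEGORIES:
        row: dict[str, object] = {"category": cat}
        members = [by_seq[s] for s, c in calls.items() if c.category == cat]
        for lib in libraries:
            uniq = sum(1 for t in members if t.count(lib) > 0)
            tot = sum(t.count(lib) for t in members)
            row[f"{lib}_unique"] = uniq
            row[f"{lib}_unique_pct"] = percent(uniq, lib_unique[lib])
            row[f"{lib}_total"] = tot
            row[f"{lib}_total_pct"] = percent(tot, lib_total[lib])
        rows.append(row)
    totals: dict[str, object] = {"category": "total"}
    for lib in libraries:
        totals[f"{lib}_unique"] = lib_unique[lib]
        totals[f"{lib}_unique_pct"] = 100.0
        totals[f"{lib}_total"] = lib_total[lib]
        totals[f"{lib}_total_pct"] = 100.0
    return pd.DataFrame([totals] + rows)


def phasing_statistic(
    starts: list[int],
    strands: list[str] | None = None,
    locus_start: int = 0,
    locus_len: int | None = None,
    phase_len: int = 21,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Register-concentration score and permutation p-value for phasing.

    Score is the largest fraction of 5' ends sharing one register modulo
    ``phase_len``. Minus-strand 5' ends are shifted by +2 before register
    assignment (the duplex-overhang correction). The null permutes start
    positions uniformly over the locus."""
    if not starts:
        raise ValueError("no 5' end positions supplied")
    if strands is not None:
        adj = [s + (2 if st == "-" else 0) for s, st in zip(starts, strands)]
    else:
        adj = list(starts)
    rng = rng or np.random.default_rng(0)
    if locus_len is None:
        locus_len = max(adj) - locus_start + 1

    def score(positions) -> float:
        regs = np.mod(np.asarray(positions) - locus_start, phase_len)
        return float(np.bincount(regs, minlength=phase_len).max() / len(positions))

    observed = score(adj)
    n = len(adj)
    exceed = 0
    for _ in range(n_permutations):
        perm = locus_start + rng.integers(0, locus_len, size=n)
        if score(perm) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return observed, p


def repeat_overlap(
    tags_with_hits: list[tuple[Tag, list[GenomeHit]]],
    repeats: list[tuple[str, int, int, str]],
) -> int:
    """Distinct tags with at least one hit fully inside a repeat interval."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _name in repeats:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    count = 0
    for tag, hits in tags_with_hits:
        inside = False
        for h in hits:
            tree = trees.get(h.chrom)
            if tree and any(iv.begin <= h.start and h.end <= iv.end
                            for iv in tree.overlap(h.start, h.end)):
                inside = True
                break
        if inside:
            count += 1
    return count
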