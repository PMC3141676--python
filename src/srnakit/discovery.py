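"""Novel-miRNA discovery from non-annotated tags.

Candidate tags (more than one read, at most 20 genome hits) have their
loci extended by 300 nt on each side; each window is folded and screened
with the hairpin precursor criteria (precursor MFE <= -18 kcal/mol, >=
16 base pairs between the mature and star arms, <= 4 bulges, mature
length 18-25 nt, mature confined to one arm, 20-nt retained flank).
Surviving precursors get a dinucleotide-shuffle stability p-value
(randfold-style) and per-library 5'-end homogeneity, and the final call
uses the paired decision rule: p <= 0.05 demands homogeneity > 0.5,
p > 0.05 demands homogeneity >= 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fold import FoldResult, fold as _fold, mfe as _mfe
from .mapping import ExactIndex, GenomeHit, map_tag
from .reads import Tag
from .sequences import revcomp, round_half_up

MFE_THRESHOLD = -18.0  # kcal/mol
MIN_PAIRED = 16
MAX_BULGES = 4
MATURE_LEN_RANGE = (18, 25)
PRECURSOR_FLANK = 20
EXTRACT_FLANK = 300
MAX_HITS = 20
DEFAULT_SHUFFLES = 199


@dataclass
class Window:
    """An extracted genomic window, oriented so the mature reads 5'->3'."""

    chrom: str
    strand: str
    gstart: int  # genomic, 0-based half-open, plus-strand coordinates
    gend: int
    seq: str
    mature: tuple[int, int]  # within-window coordinates

    def to_genomic(self, interval: tuple[int, int]) -> tuple[int, int]:
        a, b = interval
        if self.strand == "+":
            return self.gstart + a, self.gstart + b
        return self.gend - b, self.gend - a


@dataclass
class HairpinCandidate:
    window: Window
    fold: FoldResult
    mature: tuple[int, int]
    star: tuple[int, int]
    paired_bases: int
    bulges: int
    mismatches: int
    precursor: tuple[int, int]  # within-window
    precursor_seq: str
    precursor_mfe: float

    @property
    def precursor_genomic(self) -> tuple[int, int]:
        return self.window.to_genomic(self.precursor)

    def location(self) -> str:
        s, e = self.precursor_genomic
        return f"{self.window.chrom}:{s + 1}:{e}:{self.window.strand}"


@dataclass
class RandfoldResult:
    observed_mfe: float
    n_shuffles: int
    p_value: float


@dataclass
class MiRNAReport:
    name: str
    location: str
    mfe: float
    length: int
    p_value: float
    homogeneity: dict[str, tuple[int, int]]  # library -> (numerator, denominator)
    bulges: int
    mismatches: int
    needs_review: bool = False

    def homogeneity_cell(self, library: str) -> str:
        num, den = self.homogeneity.get(library, (0, 0))
        return f"{num}/{den}"


def select_candidates(tags: list[Tag], hits_by_tag: dict[str, list[GenomeHit]],
                      max_hits: int = MAX_HITS) -> list[Tag]:
    """Tags with more than one redundant read and 1..max_hits genome hits."""
    out = []
    for t in tags:
        hits = hits_by_tag.get(t.sequence, [])
        if t.total > 1 and 1 <= len(hits) <= max_hits:
            out.append(t)
    return out


def extract_window(hit: GenomeHit, genome: dict[str, str], flank: int = EXTRACT_FLANK) -> Window:
    """Extend a hit by ``flank`` nt on each side (clipped at chromosome
    ends); minus-strand windows are reverse complemented so the mature
    always reads 5'->3' within the window."""
    chrom_seq = genome[hit.chrom]
    gstart = max(0, hit.start - flank)
    gend = min(len(chrom_seq), hit.end + flank)
    raw = chrom_seq[gstart:gend]
    if hit.strand == "+":
        return Window(hit.chrom, "+", gstart, gend, raw, (hit.start - gstart, hit.end - gstart))
    return Window(hit.chrom, "-", gstart, gend, revcomp(raw), (gend - hit.end, gend - hit.start))


def hairpin_check(
    window: Window | str,
    mature: tuple[int, int] | None = None,
    fold_result: FoldResult | None = None,
    flank: int = PRECURSOR_FLANK,
) -> HairpinCandidate | str:
    """Screen a folded window against the precursor criteria.

    Returns a HairpinCandidate on acceptance, otherwise a short rejection
    reason: "mature-length", "energy", "loop-spanning", "pairs" or
    "bulges"."""
    if isinstance(window, str):
        window = Window("", "+", 0, len(window), window, mature or (0, 0))
    if mature is None:
        mature = window.mature
    mstart, mend = mature
    if not MATURE_LEN_RANGE[0] <= mend - mstart <= MATURE_LEN_RANGE[1]:
        return "mature-length"
    if fold_result is None:
        fold_result = _fold(window.seq)
    # a precursor is a subsequence of the window, so its MFE cannot be
    # below the window's: a window above threshold can be rejected outright
    if fold_result.mfe > MFE_THRESHOLD:
        return "energy"
    pairs = fold_result.pairs()
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    in_mature = lambda x: mstart <= x < mend
    if any(in_mature(i) and in_mature(j) for i, j in pairs):
        return "loop-spanning"  # mature folds onto itself across the loop
    mature_pairs = sorted((m, partner[m]) for m in range(mstart, mend) if m in partner)
    if len(mature_pairs) < MIN_PAIRED:
        return "pairs"
    partners = [p for _, p in mature_pairs]
    if min(partners) < mstart and max(partners) >= mend:
        return "loop-spanning"  # star on both sides: mature spans the loop
    paired_bases = len(mature_pairs)
    # walk the mature:star duplex interruptions; the symmetric part of each
    # interruption contributes mismatched positions, the asymmetric part
    # bulged-out bases. Counting bulges in bases (not events) is what keeps
    # the star arm commensurate with the mature arm.
    bulges = mismatches = 0
    for (m1, p1), (m2, p2) in zip(mature_pairs, mature_pairs[1:]):
        gap_m = m2 - m1 - 1
        gap_s = p1 - p2 - 1
        mismatches += min(gap_m, gap_s)
        bulges += abs(gap_m - gap_s)
    if bulges > MAX_BULGES:
        return "bulges"
    star = (min(partners), max(partners) + 1)
    pstart = max(0, min(mstart, star[0]) - flank)
    pend = min(len(window.seq), max(mend, star[1]) + flank)
    pseq = window.seq[pstart:pend]
    pmfe = _mfe(pseq)
    if pmfe > MFE_THRESHOLD:
        return "energy"
    return HairpinCandidate(
        window, fold_result, (mstart, mend), star, paired_bases, bulges, mismatches,
        (pstart, pend), pseq, pmfe,
    )


SEARCH_FLANKS = (40, 75, 150, EXTRACT_FLANK)


def subwindow(window: Window, a: int, b: int) -> Window:
    """A sub-interval [a, b) of a window as its own Window (genomic
    coordinates preserved through the parent's orientation)."""
    a = max(0, a)
    b = min(len(window.seq), b)
    if window.strand == "+":
        gstart, gend = window.gstart + a, window.gstart + b
    else:
        gstart, gend = window.gend - b, window.gend - a
    return Window(window.chrom, window.strand, gstart, gend, window.seq[a:b],
                  (window.mature[0] - a, window.mature[1] - a))


def hairpin_search(window: Window, flanks: tuple[int, ...] = SEARCH_FLANKS
                   ) -> HairpinCandidate | list[str]:
    """Hairpin screen over a cascade of search scales.

    The MFE structure of the full extraction window can bury a genuine
    stem-loop under pairings with distant flanking sequence, so the
    criteria are evaluated on nested subwindows around the mature, small
    to large; the first scale whose MFE structure passes wins (a hairpin
    that is optimal for some subwindow is a bona fide secondary structure
    of the extracted region). Returns the candidate or all rejection
    reasons."""
    mstart, mend = window.mature
    reasons = []
    for flank in flanks:
        win = subwindow(window, mstart - flank, mend + flank)
        outcome = hairpin_check(win)
        if isinstance(outcome, str):
            reasons.append(outcome)
        else:
            return outcome
    return reasons


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: a random sequence with the same
    mononucleotide and dinucleotide multisets and the same first and last
    base (random Eulerian walk on the dinucleotide multigraph)."""
    s = sequence.upper()
    if len(s) <= 3 or len(set(s)) == 1:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges.keys())
    non_final = [v for v in vertices if v != last]
    for _ in range(1000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in non_final}
        # the chosen last edges must lead every vertex to the final one
        ok = True
        for v in non_final:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        return s
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        ordered[v] = rest
    out = [s[0]]
    cur = s[0]
    pos = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        nxt = ordered[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def randfold_p(precursor: str, n_shuffles: int = DEFAULT_SHUFFLES,
               rng: np.random.Generator | None = None) -> RandfoldResult:
    """Dinucleotide-shuffle stability test.

    p = (1 + #{shuffled MFE <= observed}) / (N + 1)."""
    rng = rng or np.random.default_rng(0)
    observed = _mfe(precursor)
    if n_shuffles == 0:
        warnings.warn("randfold with 0 shuffles is degenerate; p = 1")
        return RandfoldResult(observed, 0, 1.0)
    hits = 0
    for _ in range(n_shuffles):
        if _mfe(dinucleotide_shuffle(precursor, rng)) <= observed + 1e-9:
            hits += 1
    return RandfoldResult(observed, n_shuffles, (1 + hits) / (n_shuffles + 1))


def five_prime_homogeneity(
    reads: list[tuple[GenomeHit, int]],
    mature_hit: GenomeHit,
    precursor_genomic: tuple[int, int],
) -> tuple[int, int]:
    """(numerator, denominator) of the 5'-homogeneity fraction.

    Denominator: redundant reads whose hit lies within the precursor
    interval on the mature strand; numerator: those sharing the mature's
    5' genomic end. Returns (0, 0) when no reads map to the precursor."""
    pstart, pend = precursor_genomic
    mature_5p = mature_hit.start if mature_hit.strand == "+" else mature_hit.end - 1
    num = den = 0
    for hit, count in reads:
        if hit.chrom != mature_hit.chrom or hit.strand != mature_hit.strand:
            continue
        if hit.start < pstart or hit.end > pend:
            continue
        den += count
        five = hit.start if hit.strand == "+" else hit.end - 1
        if five == mature_5p:
            num += count
    return num, den


def homogeneity_fraction(num: int, den: int) -> float:
    return num / den if den else 0.0


def decide(p_value: float, homogeneity: dict[str, tuple[int, int]]) -> tuple[bool, str, str]:
    """Accept/reject by the paired stability/homogeneity rule.

    The rule is evaluated in the best library (largest fraction among
    libraries with mapped precursor reads). Returns (accept, reason,
    best_library)."""
    best_lib, best_h = "", 0.0
    for lib, (num, den) in homogeneity.items():
        if den == 0:
            continue
        h = num / den
        if h > best_h or not best_lib:
            best_lib, best_h = lib, h
    if p_value <= 0.05:
        ok = best_h > 0.5
        reason = "" if ok else f"homogeneity {best_h:.3f} <= 0.5 at p <= 0.05"
    else:
        ok = best_h >= 0.75
        reason = "" if ok else f"homogeneity {best_h:.3f} < 0.75 at p > 0.05"
    return ok, reason, best_lib


def _needs_review(candidate: HairpinCandidate, p_value: float, best_h: float) -> bool:
    """Near-threshold candidates are flagged for manual review (the
    mechanical stand-in for published manual-rechecking criteria)."""
    checks = [
        abs(candidate.precursor_mfe - MFE_THRESHOLD) <= 0.1 * abs(MFE_THRESHOLD),
        candidate.paired_bases <= MIN_PAIRED + 1,
        candidate.bulges >= MAX_BULGES,
        abs(p_value - 0.05) <= 0.005,
        abs(best_h - (0.5 if p_value <= 0.05 else 0.75)) <= 0.075,
    ]
    return any(checks)


@dataclass
class DiscoveryResult:
    accepted: list[MiRNAReport] = field(default_factory=list)
    rejected: list[dict] = field(default_factory=list)

    def to_frame(self, libraries: list[str]) -> pd.DataFrame:
        rows = []
        for r in self.accepted:
            row = {
                "name": r.name, "location": r.location, "mfe": round(r.mfe, 2),
                "len": r.length, "P-value": r.p_value,
            }
            for lib in libraries:
                row[lib] = r.homogeneity_cell(lib)
            row["bulges"] = r.bulges
            row["mismatched"] = r.mismatches
            row["needs_review"] = r.needs_review
            rows.append(row)
        return pd.DataFrame(rows)


def report_summary(reports: list[MiRNAReport]) -> dict[str, float]:
    """Length range/floor-mean and MFE range/two-decimal-mean over the
    accepted precursors; empty dict for an empty accept set."""
    if not reports:
        return {}
    lengths = [r.length for r in reports]
    mfes = [r.mfe for r in reports]
    return {
        "n": len(reports),
        "len_min": min(lengths),
        "len_max": max(lengths),
        "len_mean_floor": int(np.floor(sum(lengths) / len(lengths))),
        "mfe_min": min(mfes),
        "mfe_max": max(mfes),
        "mfe_mean": round_half_up(sum(mfes) / len(mfes), 2),
    }


def discover(
    tags: list[Tag],
    candidate_tags: list[Tag],
    hits_by_tag: dict[str, list[GenomeHit]],
    genome: dict[str, str],
    libraries: list[str],
    n_shuffles: int = DEFAULT_SHUFFLES,
    rng: np.random.Generator | None = None,
    flank: int = EXTRACT_FLANK,
) -> DiscoveryResult:
    """Full discovery pass over candidate tags.

    For a multi-hit tag every hit is folded and the accepted hairpin with
    the lowest precursor MFE is reported (each miRNA is assigned a single
    precursor locus)."""
    rng = rng or np.random.default_rng(0)
    reads_by_lib = {
        lib: [(h, t.count(lib)) for t in tags if t.count(lib) > 0
              for h in hits_by_tag.get(t.sequence, [])]
        for lib in libraries
    }
    result = DiscoveryResult()
    n_named = 0
    for tag in candidate_tags:
        best: HairpinCandidate | None = None
        best_hit: GenomeHit | None = None
        reasons = []
        for hit in hits_by_tag.get(tag.sequence, []):
            window = extract_window(hit, genome, flank=flank)
            outcome = hairpin_search(window)
            if isinstance(outcome, list):
                reasons.extend(outcome)
                continue
            if best is None or outcome.precursor_mfe < best.precursor_mfe:
                best, best_hit = outcome, hit
        if best is None:
            result.rejected.append({"tag": tag.sequence, "stage": "hairpin",
                                    "reasons": sorted(set(reasons))})
            continue
        rf = randfold_p(best.precursor_seq, n_shuffles, rng)
        homog = {
            lib: five_prime_homogeneity(reads_by_lib[lib], best_hit, best.precursor_genomic)
            for lib in libraries
        }
        accept, reason, best_lib = decide(rf.p_value, homog)
        best_h = homogeneity_fraction(*homog.get(best_lib, (0, 0)))
        if not accept:
            result.rejected.append({"tag": tag.sequence, "stage": "decide", "reasons": [reason],
                                    "p_value": rf.p_value})
            continue
        n_named += 1
        result.accepted.append(
            MiRNAReport(
                name=f"candidate-miR-{n_named}",
                location=best.location(),
                mfe=best.precursor_mfe,
                length=best.precursor[1] - best.precursor[0],
                p_value=rf.p_value,
                homogeneity=homog,
                bulges=best.bulges,
                mismatches=best.mismatches,
                needs_review=_needs_review(best, rf.p_value, best_h),
            )
        )
    return result
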