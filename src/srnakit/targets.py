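"""Rule-based miRNA target prediction on transcript sequences.

Candidate sites are found by scanning the transcript with an
antiparallel duplex alignment (seed positions 2-8 from the miRNA 5' end
weighted by a scaling factor, miRanda-style score and energy
thresholds), then filtered with position-specific mismatch rules:

strict  - <= 4 weighted mismatches at positions 2-21; no run of more
          than 2 adjacent mismatches; no adjacent mismatches at 2-12;
          strict Watson-Crick at 10-11; <= 2.5 weighted mismatches at
          1-12 (G:U = 0.5 everywhere); duplex MFE > 74% of the MFE
          against the perfect complement.
relaxed - only the <= 4 weighted mismatches at 2-21 rule (position 1
          and positions beyond 21 ignored).

Positions are 1-based from the miRNA 5' end. The duplex energy reuses
the stacking table of the hairpin folding engine restricted to
intermolecular pairs, which keeps the 74% MFE ratio internally
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import PAIR_INDEX, STACK
from .sequences import BASE_CODE, revcomp

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
GU_PAIRS = {("G", "T"), ("T", "G"), ("G", "U"), ("U", "G")}

SEED_RANGE = (2, 8)  # 1-based miRNA positions whose contributions are scaled


@dataclass
class DuplexScoringParams:
    min_score: float = 90.0
    max_energy: float = -20.0  # kcal/mol
    scaling: float = 2.0  # seed weight multiplier
    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch_score: float = -3.0
    gap_score: float = -9.0

    def validate(self) -> "DuplexScoringParams":
        if self.scaling < 1:
            raise ValueError("scaling must be >= 1")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        return self


@dataclass
class DuplexAlignment:
    """A miRNA:target pairing with per-position states.

    ``states[k]`` describes miRNA position k+1 (1-based from the 5' end)
    as "WC", "GU", "MM" or "GAP". ``target_window`` is the transcript
    segment (5'->3') the miRNA pairs with; ``target_start`` its 0-based
    transcript offset."""

    mirna: str
    target_window: str
    target_start: int
    states: list[str]
    score: float
    duplex_energy: float


@dataclass
class RuleVerdict:
    mm_2_21: bool
    adjacent_total: bool
    adjacent_2_12: bool
    perfect_10_11: bool
    weighted_1_12: bool
    mfe_ratio: bool
    ratio_value: float = float("nan")
    weighted_mm_1_12: float = float("nan")

    @property
    def overall(self) -> bool:
        return all([self.mm_2_21, self.adjacent_total, self.adjacent_2_12,
                    self.perfect_10_11, self.weighted_1_12, self.mfe_ratio])


def pair_state(mirna_base: str, target_base: str) -> str:
    """State of one duplex position (bases given 5'->3' on each strand)."""
    key = (mirna_base.upper(), target_base.upper())
    if key in WC_PAIRS:
        return "WC"
    if key in GU_PAIRS:
        return "GU"
    return "MM"


def duplex_states(mirna: str, target_window: str) -> list[str]:
    """Antiparallel pairing states: miRNA position k (from its 5' end)
    faces target position L-1-k of the window (the window read 5'->3')."""
    L = len(mirna)
    if len(target_window) != L:
        raise ValueError("gapless duplex needs equal lengths")
    return [pair_state(mirna[k], target_window[L - 1 - k]) for k in range(L)]


def duplex_energy(mirna: str, target_window: str, states: list[str] | None = None) -> float:
    """Stacking energy of the intermolecular duplex (kcal/mol): every two
    consecutive paired positions contribute one stack term."""
    states = states or duplex_states(mirna, target_window)
    L = len(mirna)
    energy = 0.0
    for k in range(L - 1):
        if states[k] in ("WC", "GU") and states[k + 1] in ("WC", "GU"):
            outer = PAIR_INDEX[BASE_CODE[mirna[k]], BASE_CODE[target_window[L - 1 - k]]]
            inner = PAIR_INDEX[BASE_CODE[mirna[k + 1]], BASE_CODE[target_window[L - 2 - k]]]
            if outer >= 0 and inner >= 0:
                energy += STACK[outer, inner]
    return energy


def duplex_score(states: list[str], params: DuplexScoringParams) -> float:
    score = 0.0
    contribution = {"WC": params.match_score, "GU": params.wobble_score,
                    "MM": params.mismatch_score, "GAP": params.gap_score}
    for k, st in enumerate(states):
        w = params.scaling if SEED_RANGE[0] <= k + 1 <= SEED_RANGE[1] else 1.0
        score += w * contribution[st]
    return score


def align_duplex(mirna: str, target_window: str, target_start: int,
                 params: DuplexScoringParams) -> DuplexAlignment:
    states = duplex_states(mirna, target_window)
    return DuplexAlignment(
        mirna=mirna.upper(),
        target_window=target_window.upper(),
        target_start=target_start,
        states=states,
        score=duplex_score(states, params),
        duplex_energy=duplex_energy(mirna.upper(), target_window.upper(), states),
    )


def scan(mirna: str, transcript: str, params: DuplexScoringParams | None = None
         ) -> list[DuplexAlignment]:
    """All transcript windows whose duplex meets both thresholds
    (score >= min_score and energy <= max_energy)."""
    params = (params or DuplexScoringParams()).validate()
    mirna = mirna.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    L = len(mirna)
    out = []
    for start in range(0, len(transcript) - L + 1):
        window = transcript[start:start + L]
        aln = align_duplex(mirna, window, start, params)
        if aln.score >= params.min_score and aln.duplex_energy <= params.max_energy:
            out.append(aln)
    return out


def classify_positions(duplex: DuplexAlignment) -> dict[str, object]:
    """Per-position states and weighted mismatch counts; gaps count as
    mismatches for every rule."""
    states = duplex.states
    return {
        "states": list(states),
        "weighted_mm_1_12": weighted_mismatches(states, 1, 12),
        "weighted_mm_2_21": weighted_mismatches(states, 2, 21),
        "n_wc": states.count("WC"),
        "n_gu": states.count("GU"),
        "n_mm": states.count("MM") + states.count("GAP"),
    }


def weighted_mismatches(states: list[str], first: int, last: int) -> float:
    """Weighted mismatch count over 1-based positions [first, last]:
    MM and GAP count 1, G:U wobbles count 0.5."""
    total = 0.0
    for pos in range(first, min(last, len(states)) + 1):
        st = states[pos - 1]
        if st in ("MM", "GAP"):
            total += 1.0
        elif st == "GU":
            total += 0.5
    return total


def _max_adjacent_mm(states: list[str], first: int, last: int) -> int:
    """Longest run of consecutive MM/GAP positions within [first, last];
    a G:U between two mismatches leaves them non-adjacent."""
    run = best = 0
    for pos in range(first, min(last, len(states)) + 1):
        if states[pos - 1] in ("MM", "GAP"):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def mfe_ratio(duplex: DuplexAlignment) -> float:
    """duplex energy / energy of the miRNA bound to its perfect
    complement, computed with the same engine on both sides."""
    perfect = revcomp(duplex.mirna.replace("U", "T"))
    ref = duplex_energy(duplex.mirna.replace("U", "T"), perfect)
    if ref == 0:
        return 0.0
    return duplex.duplex_energy / ref


def rule_filter_strict(duplex: DuplexAlignment, min_ratio: float = 0.74) -> RuleVerdict:
    states = duplex.states
    L = len(states)
    ratio = mfe_ratio(duplex)
    return RuleVerdict(
        mm_2_21=weighted_mismatches(states, 2, 21) <= 4.0,
        adjacent_total=_max_adjacent_mm(states, 1, L) <= 2,
        adjacent_2_12=_max_adjacent_mm(states, 2, 12) <= 1,
        perfect_10_11=all(states[p - 1] == "WC" for p in (10, 11) if p <= L),
        weighted_1_12=weighted_mismatches(states, 1, 12) <= 2.5,
        mfe_ratio=ratio > min_ratio,
        ratio_value=ratio,
        weighted_mm_1_12=weighted_mismatches(states, 1, 12),
    )


def rule_filter_relaxed(duplex: DuplexAlignment) -> RuleVerdict:
    """Only the positions-2-21 mismatch budget is enforced; position 1 and
    positions beyond 21 are ignored entirely."""
    states = duplex.states
    passed = weighted_mismatches(states, 2, 21) <= 4.0
    return RuleVerdict(
        mm_2_21=passed,
        adjacent_total=True,
        adjacent_2_12=True,
        perfect_10_11=True,
        weighted_1_12=True,
        mfe_ratio=True,
        weighted_mm_1_12=weighted_mismatches(states, 1, 12),
    )


@dataclass
class TargetSite:
    mirna_name: str
    gene_id: str
    start: int  # 0-based on transcript
    end: int
    alignment: DuplexAlignment
    strict: RuleVerdict = field(default=None)  # type: ignore[assignment]
    relaxed: RuleVerdict = field(default=None)  # type: ignore[assignment]


def predict_targets(
    mirnas: list[tuple[str, str]],
    transcripts: list[tuple[str, str]],
    params: DuplexScoringParams | None = None,
    mode: str = "both",
) -> list[TargetSite]:
    """Scan every miRNA against every transcript and attach rule verdicts."""
    params = (params or DuplexScoringParams()).validate()
    sites = []
    for mname, mseq in mirnas:
        for gid, tseq in transcripts:
            for aln in scan(mseq, tseq, params):
                site = TargetSite(mname, gid, aln.target_start,
                                  aln.target_start + len(aln.target_window), aln)
                if mode in ("both", "strict"):
                    site.strict = rule_filter_strict(aln)
                if mode in ("both", "relaxed"):
                    site.relaxed = rule_filter_relaxed(aln)
                sites.append(site)
    return sites


def render_duplex(aln: DuplexAlignment) -> str:
    """Three-line ASCII duplex: target 5'->3', pairing line, miRNA 3'->5'."""
    tgt = aln.target_window
    mir_rev = aln.mirna[::-1]
    marks = []
    for k in range(len(tgt)):
        st = aln.states[len(tgt) - 1 - k]
        marks.append("|" if st == "WC" else ("o" if st == "GU" else " "))
    return (f"5' {tgt} 3'  target\n   {''.join(marks)}\n3' {mir_rev} 5'  miRNA")
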