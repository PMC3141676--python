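"""RNA secondary-structure prediction for hairpin screening.

The default engine is a nested-structure (pseudoknot-free) dynamic
program over a stacking energy model:

* admissible pairs: Watson-Crick (A:U, G:C) and the G:U wobble;
* a hairpin loop must contain at least 3 unpaired bases;
* unpaired bases contribute 0 kcal/mol;
* two directly stacked pairs (i,j) on (i+1,j-1) contribute the
  nearest-neighbour stacking free energy of that pair step.

The stacking table is a standard set of nearest-neighbour free energies
at 37 degC (kcal/mol); the two mildly destabilising G:U-on-G:U steps are
clamped to zero so that every stack term is non-positive, which keeps
the dynamic-programming decomposition exact and guarantees mfe <= 0.
Every helix additionally pays a +3.5 kcal/mol initiation penalty
(charged on the pair whose interior neighbour is unpaired) -- the
minimal analogue of the loop-initiation terms in full thermodynamic
models. Without it, fragmented chance duplexes in random sequence score
as well as clean stems.

The model is deliberately simpler than a full Turner model (no
loop-size dependence, no dangles); it ranks stem-loops by how much
contiguous helix they contain, which is what the hairpin filters need.
Energies are not expected to match mfold/ViennaRNA numerically; the
``engine="vienna"`` backend (ViennaRNA python bindings, if importable)
can be plugged in where thermodynamic parity matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .sequences import encode, to_rna

MIN_LOOP = 3  # minimum unpaired bases closed by a hairpin pair

# pair codes: AU=0, CG=1, GC=2, UA=3, GU=4, UG=5; -1 = not pairable
PAIR_INDEX = -np.ones((4, 4), dtype=np.int8)
for _idx, (_a, _b) in enumerate([(0, 3), (1, 2), (2, 1), (3, 0), (2, 3), (3, 2)]):
    PAIR_INDEX[_a, _b] = _idx

# STACK[outer, inner]: outer pair (i,j) stacked on inner pair (i+1,j-1)
STACK = np.array(
    [
        # AU     CG     GC     UA     GU     UG   <- inner
        [-0.9, -2.2, -2.1, -1.1, -0.6, -1.4],  # AU
        [-2.1, -3.3, -2.4, -2.1, -1.4, -2.1],  # CG
        [-2.4, -3.4, -3.3, -2.2, -1.5, -2.5],  # GC
        [-1.3, -2.4, -2.1, -0.9, -1.0, -1.3],  # UA
        [-1.3, -2.5, -2.1, -1.4, -0.5, 0.0],  # GU
        [-1.0, -1.5, -1.4, -0.6, 0.0, -0.5],  # UG
    ],
    dtype=np.float64,
)

HELIX_INIT = 3.5  # kcal/mol, charged once per helix

INF = 1e30


@dataclass(frozen=True)
class FoldResult:
    """A predicted structure (dot-bracket) and its free energy (kcal/mol)."""

    structure: str
    mfe: float

    def pairs(self) -> list[tuple[int, int]]:
        return dotbracket_to_pairs(self.structure)


@njit(cache=True)
def _fill(codes, pair_index, stack, helix_init):  # pragma: no cover - jitted
    n = codes.shape[0]
    W = np.zeros((n, n), dtype=np.float64)
    V = np.full((n, n), INF, dtype=np.float64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            pij = pair_index[codes[i], codes[j]]
            if pij >= 0:
                best = W[i + 1, j - 1] + helix_init
                if j - 1 - (i + 1) > MIN_LOOP:
                    pin = pair_index[codes[i + 1], codes[j - 1]]
                    if pin >= 0 and V[i + 1, j - 1] < INF:
                        cand = V[i + 1, j - 1] + stack[pij, pin]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # W recursion
            w = W[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if pair_index[codes[i], codes[k]] >= 0 and V[i, k] < INF:
                    rest = W[k + 1, j] if k + 1 <= j else 0.0
                    cand = V[i, k] + rest
                    if cand < w:
                        w = cand
            W[i, j] = w
    return W, V


def _traceback(codes: np.ndarray, W: np.ndarray, V: np.ndarray) -> list[tuple[int, int]]:
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    tol = 1e-9
    stack_frames: list[tuple[str, int, int]] = [("W", 0, n - 1)] if n > 1 else []
    while stack_frames:
        kind, i, j = stack_frames.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if kind == "W":
            if abs(W[i, j] - W[i + 1, j]) <= tol:
                stack_frames.append(("W", i + 1, j))
                continue
            found = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if PAIR_INDEX[codes[i], codes[k]] < 0 or V[i, k] >= INF:
                    continue
                rest = W[k + 1, j] if k + 1 <= j else 0.0
                if abs(W[i, j] - (V[i, k] + rest)) <= tol:
                    stack_frames.append(("V", i, k))
                    if k + 1 <= j:
                        stack_frames.append(("W", k + 1, j))
                    found = True
                    break
            if not found:  # numerical safety net; fall back to open chain
                stack_frames.append(("W", i + 1, j))
        else:  # V: (i, j) is paired
            pairs.append((i, j))
            pij = PAIR_INDEX[codes[i], codes[j]]
            if j - 1 - (i + 1) > MIN_LOOP:
                pin = PAIR_INDEX[codes[i + 1], codes[j - 1]]
                if (
                    pin >= 0
                    and V[i + 1, j - 1] < INF
                    and abs(V[i, j] - (V[i + 1, j - 1] + STACK[pij, pin])) <= tol
                ):
                    stack_frames.append(("V", i + 1, j - 1))
                    continue
            # helix ends here; interior re-opens freely
            stack_frames.append(("W", i + 1, j - 1))
    return sorted(pairs)


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for k, c in enumerate(structure):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), k))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def structure_energy(sequence: str, pairs: list[tuple[int, int]]) -> float:
    """Free energy of an explicit set of pairs under the stacking model.

    Used both by the engine (implicitly, through its recursion) and by
    enumeration-based cross checks: the search strategies differ but the
    energy model must be shared for the comparison to mean anything.
    """
    codes = encode(to_rna(sequence))
    seen = set()
    for i, j in pairs:
        if not (0 <= i < j < len(codes)):
            raise ValueError(f"pair ({i},{j}) out of range")
        if j - i <= MIN_LOOP:
            raise ValueError(f"pair ({i},{j}) closes a loop shorter than {MIN_LOOP}")
        if PAIR_INDEX[codes[i], codes[j]] < 0:
            raise ValueError(f"inadmissible pair at ({i},{j})")
        if i in seen or j in seen:
            raise ValueError("position paired twice")
        seen.add(i)
        seen.add(j)
    pair_set = set(pairs)
    energy = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pair_set:
            outer = PAIR_INDEX[codes[i], codes[j]]
            inner = PAIR_INDEX[codes[i + 1], codes[j - 1]]
            energy += STACK[outer, inner]
        else:
            energy += HELIX_INIT  # innermost pair of its helix
    return energy


def fold(sequence: str, engine: str = "stack") -> FoldResult:
    """Fold a sequence and return dot-bracket structure plus MFE.

    Parameters
    ----------
    sequence : DNA or RNA string (T is mapped to U); length <= 1000.
    engine : "stack" (default, in-package DP) or "vienna" (ViennaRNA
        bindings, if installed).
    """
    rna = to_rna(sequence)
    if len(rna) > 1000:
        raise ValueError(f"sequence of length {len(rna)} exceeds the 1000-nt fold limit")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU symbols {sorted(bad)} after T->U mapping")
    if engine == "vienna":
        return _fold_vienna(rna)
    if engine != "stack":
        raise ValueError(f"unknown folding engine {engine!r}")
    if len(rna) <= MIN_LOOP + 1:
        return FoldResult("." * len(rna), 0.0)
    codes = encode(rna)
    W, V = _fill(codes, PAIR_INDEX, STACK, HELIX_INIT)
    pairs = _traceback(codes, W, V)
    return FoldResult(pairs_to_dotbracket(len(rna), pairs), float(W[0, len(rna) - 1]))


def mfe(sequence: str) -> float:
    """MFE only (skips traceback); used by the shuffle test's inner loop."""
    rna = to_rna(sequence)
    if len(rna) <= MIN_LOOP + 1:
        return 0.0
    W, _ = _fill(encode(rna), PAIR_INDEX, STACK, HELIX_INIT)
    return float(W[0, len(rna) - 1])


def _fold_vienna(rna: str) -> FoldResult:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("ViennaRNA python bindings are not installed") from exc
    structure, energy = RNA.fold(rna)
    return FoldResult(structure, float(energy))
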