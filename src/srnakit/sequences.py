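"""Low-level sequence helpers shared across the pipeline.

All genomic sequences are handled as uppercase DNA strings over ACGT;
folding converts to RNA internally. Coordinates are 0-based half-open
everywhere in memory and rendered 1-based inclusive only in reports.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA_ALPHABET = "ACGT"

# base -> integer code used by the folding kernels (U and T collapse)
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U maps to A)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def validate_dna(seq: str, allow_n: bool = False) -> str:
    """Uppercase and validate a DNA string; raises ValueError on bad symbols."""
    s = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-DNA symbols {sorted(bad)} in sequence {s[:30]!r}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode ACGT/U into int8 codes for the numeric folding kernels."""
    try:
        return np.array([BASE_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"cannot encode base {exc.args[0]!r}") from exc


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention used in the report tables.

    numpy/python banker's rounding would turn 0.125 -> 0.12; table
    percentages use the familiar 0.13.
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = np.floor(np.abs(scaled) + 0.5) * np.sign(scaled)
    out = rounded / factor
    return float(out) if ndigits > 0 else float(int(out))
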