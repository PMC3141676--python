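"""Raw-read cleanup, tag collapsing and descriptive library summaries.

A *tag* is a unique insert sequence with per-library redundant read
counts; "unique" numbers count tags, "total" numbers count reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import round_half_up

ADAPTER_KEY_LEN = 8  # adapter recognised by exact match of its first k nt


@dataclass
class Tag:
    """A unique small-RNA sequence with per-library redundant counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)


@dataclass
class TrimStats:
    input_reads: int = 0
    kept: int = 0
    no_adapter: int = 0
    low_quality: int = 0
    too_short: int = 0
    too_long: int = 0

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


@dataclass
class LibrarySummary:
    library: str
    total_reads: int
    unique_tags: int
    singleton_tags: int
    length_histogram: dict[int, int]  # tag length -> unique-tag count
    base_fractions: np.ndarray  # positions x 4 (A,C,G,T)

    @property
    def singleton_percent(self) -> int:
        """Whole-percent singleton share, the headline per-library figure."""
        return singleton_percent(self.unique_tags, self.singleton_tags)


def singleton_percent(unique_tags: int, singleton_tags: int) -> int:
    if unique_tags == 0:
        return 0
    return int(round_half_up(100.0 * singleton_tags / unique_tags))


def trim_and_filter(
    reads: list[tuple[str, str, str]] | list[tuple[str, str]],
    adapter3: str,
    adapter5: str = "",
    min_len: int = 18,
    max_len: int = 30,
    min_quality: int = 20,
) -> tuple[list[str], TrimStats]:
    """Remove adapters, drop low-quality and out-of-range reads.

    ``reads`` are (id, sequence[, quality-string]) tuples. The 3' adapter
    is located by an exact match of its first 8 nt; the leftmost
    occurrence marks the insert end. Reads with no detectable 3' adapter
    are dropped as unligated artifacts: a genuine 18-28 nt insert must
    read through into the adapter on this platform. A leading 5'-adapter
    carry-over is stripped when present. Any N or any base below
    ``min_quality`` (phred33) fails the read.
    """
    if not adapter3:
        raise ValueError("adapter3 must be a non-empty sequence")
    key = adapter3.upper()[:ADAPTER_KEY_LEN]
    a5 = adapter5.upper()
    stats = TrimStats()
    kept: list[str] = []
    for item in reads:
        rid, seq = item[0], item[1].upper()
        qual = item[2] if len(item) > 2 else None
        stats.input_reads += 1
        pos = seq.find(key)
        if pos < 0:
            stats.no_adapter += 1
            continue
        insert = seq[:pos]
        if a5 and insert.startswith(a5):
            insert = insert[len(a5):]
        if "N" in insert:
            stats.low_quality += 1
            continue
        if qual is not None and any(ord(c) - 33 < min_quality for c in qual[: len(insert)]):
            stats.low_quality += 1
            continue
        if len(insert) < min_len:
            stats.too_short += 1
            continue
        if len(insert) > max_len:
            stats.too_long += 1
            continue
        stats.kept += 1
        kept.append(insert)
    return kept, stats


def collapse(clean_reads: dict[str, list[str]]) -> list[Tag]:
    """Collapse per-library clean reads into unique tags with counts.

    Conservation: for every library, the tag counts re-sum to the number
    of clean reads supplied for it."""
    tags: dict[str, Tag] = {}
    for lib, seqs in clean_reads.items():
        for seq in seqs:
            tag = tags.get(seq)
            if tag is None:
                tag = tags[seq] = Tag(seq)
            tag.counts[lib] = tag.counts.get(lib, 0) + 1
    return sorted(tags.values(), key=lambda t: t.sequence)


BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASE_ORDER)}


def summarize_library(tags: list[Tag], library: str, max_positions: int = 24) -> LibrarySummary:
    present = [t for t in tags if t.count(library) > 0]
    total = sum(t.count(library) for t in present)
    singletons = sum(1 for t in present if t.count(library) == 1)
    hist: dict[int, int] = {}
    for t in present:
        hist[len(t.sequence)] = hist.get(len(t.sequence), 0) + 1
    return LibrarySummary(
        library=library,
        total_reads=total,
        unique_tags=len(present),
        singleton_tags=singletons,
        length_histogram=dict(sorted(hist.items())),
        base_fractions=position_base_bias(present, mode="unique", library=library,
                                          max_positions=max_positions),
    )


def position_base_bias(
    tags: list[Tag],
    mode: str = "unique",
    library: str | None = None,
    max_positions: int = 24,
) -> np.ndarray:
    """Per-position base fractions over positions 1..max_positions.

    ``mode="unique"`` weights every tag once; ``mode="total"`` weights by
    redundant counts (library-restricted if a library is given).
    Positions beyond a tag's length do not contribute for that tag; rows
    with no contributions are returned as NaN."""
    if mode not in ("unique", "total"):
        raise ValueError("mode must be 'unique' or 'total'")
    counts = np.zeros((max_positions, 4), dtype=float)
    for t in tags:
        if library is not None:
            w = t.count(library) if mode == "total" else (1 if t.count(library) > 0 else 0)
        else:
            w = t.total if mode == "total" else 1
        if w == 0:
            continue
        for pos, base in enumerate(t.sequence[:max_positions]):
            counts[pos, _BASE_IDX[base]] += w
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, counts / sums, np.nan)


@dataclass
class OverlapReport:
    """Common/specific tag accounting between two libraries."""

    lib_a: str
    lib_b: str
    unique_a: int
    unique_b: int
    common_unique: int
    total_a: int
    total_b: int
    common_total: int  # redundant reads of shared tag sequences, both libraries
    a_specific_total: int
    b_specific_total: int

    @property
    def unique_union(self) -> int:
        return self.unique_a + self.unique_b - self.common_unique

    @property
    def total_denominator(self) -> int:
        return self.total_a + self.total_b

    def percentages(self) -> dict[str, float]:
        return {
            "common_unique": percent(self.common_unique, self.unique_union),
            "a_specific_unique": percent(self.unique_a - self.common_unique, self.unique_union),
            "b_specific_unique": percent(self.unique_b - self.common_unique, self.unique_union),
            "common_total": percent(self.common_total, self.total_denominator),
            "a_specific_total": percent(self.a_specific_total, self.total_denominator),
            "b_specific_total": percent(self.b_specific_total, self.total_denominator),
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            ("Total_sRNAs", self.unique_union, 100.0, self.total_denominator, 100.0),
            (f"{self.lib_a}_&_{self.lib_b}", self.common_unique, pct["common_unique"],
             self.common_total, pct["common_total"]),
            (f"{self.lib_a}_specific", self.unique_a - self.common_unique,
             pct["a_specific_unique"], self.a_specific_total, pct["a_specific_total"]),
            (f"{self.lib_b}_specific", self.unique_b - self.common_unique,
             pct["b_specific_unique"], self.b_specific_total, pct["b_specific_total"]),
        ]
        return pd.DataFrame(rows, columns=["Class", "Unique_sRNA", "Unique_percent",
                                           "Total_sRNA", "Total_percent"])


def percent(numerator: int | float, denominator: int | float) -> float:
    """Two-decimal percentage, rounded half up (report-table convention)."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 2)


def compare_samples(tags: list[Tag], lib_a: str, lib_b: str) -> OverlapReport:
    ua = ub = cu = ta = tb = ct = ast = bst = 0
    for t in tags:
        ca, cb = t.count(lib_a), t.count(lib_b)
        ta += ca
        tb += cb
        if ca > 0:
            ua += 1
        if cb > 0:
            ub += 1
        if ca > 0 and cb > 0:
            cu += 1
            ct += ca + cb
        elif ca > 0:
            ast += ca
        elif cb > 0:
            bst += cb
    return OverlapReport(lib_a, lib_b, ua, ub, cu, ta, tb, ct, ast, bst)
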