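"""Published count tables bundled with the package, plus the arithmetic
that turns them into report figures.

The three deep-sequenced diatom libraries (normal, nitrogen-limited and
silicon-limited cultures; PT1-PT3) are summarised in the literature only
as printed count tables. Those counts ship here as plain TSV inputs so
the reporting arithmetic (singleton shares, category percentages,
pairwise overlap percentages, precursor summary statistics) can be
recomputed and checked against the printed figures.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .reads import percent, singleton_percent
from .sequences import round_half_up


def _data_path(name: str):
    return str(importlib.resources.files("srnakit.data") / name)


def load_library_counts() -> pd.DataFrame:
    """Per-library totals: reads, unique tags, genome/plastid matches,
    singletons."""
    return pd.read_csv(_data_path("pti_library_counts.tsv"), sep="\t", comment="#")


def load_category_counts() -> pd.DataFrame:
    """Annotation-category unique/total counts per library."""
    return pd.read_csv(_data_path("pti_category_counts.tsv"), sep="\t", comment="#")


def load_pairwise_overlaps() -> pd.DataFrame:
    """Common/specific tag counts between every two libraries."""
    return pd.read_csv(_data_path("pti_pairwise_overlaps.tsv"), sep="\t", comment="#")


def load_premirna_characteristics() -> pd.DataFrame:
    """The 13 published pre-miRNA records (location, MFE, length, shuffle
    p-value, per-library homogeneity cells, bulge/mismatch counts)."""
    return pd.read_csv(_data_path("pti_premirna_characteristics.tsv"), sep="\t", comment="#")


def library_singleton_percents() -> dict[str, int]:
    df = load_library_counts()
    return {
        row["sample"]: singleton_percent(int(row["unique_srna"]), int(row["singleton_unique"]))
        for _, row in df.iterrows()
    }


def category_percent(sample: str, category: str, kind: str = "unique") -> float:
    """Two-decimal category share for one library (kind: unique|total)."""
    df = load_category_counts().set_index("category")
    col = f"{sample}_{kind}"
    return percent(int(df.loc[category, col]), int(df.loc["total", col]))


def overlap_percentages(pair: str) -> dict[str, float | int]:
    """Recomputed overlap report for one library pair (e.g. "PT1_PT2")."""
    df = load_pairwise_overlaps().set_index("pair")
    row = df.loc[pair]
    lib_counts = load_library_counts().set_index("sample")
    a, b = pair.split("_")
    unique_a = int(lib_counts.loc[a, "unique_srna"])
    unique_b = int(lib_counts.loc[b, "unique_srna"])
    total_a = int(lib_counts.loc[a, "total_srna"])
    total_b = int(lib_counts.loc[b, "total_srna"])
    common = int(row["common_unique"])
    union = unique_a + unique_b - common
    return {
        "unique_union": union,
        "total_denominator": total_a + total_b,
        "common_unique_pct": percent(common, union),
        "a_specific_unique_pct": percent(int(row["a_specific_unique"]), union),
        "b_specific_unique_pct": percent(int(row["b_specific_unique"]), union),
        "common_total_pct": percent(int(row["common_total"]), total_a + total_b),
    }


def premirna_summary() -> dict[str, float]:
    """Summary statistics recomputed from the 13 published precursor rows
    (length range and floor-mean, MFE range and two-decimal mean)."""
    df = load_premirna_characteristics()
    lengths = df["len"].astype(int)
    mfes = df["mfe"].astype(float)
    return {
        "n": int(len(df)),
        "len_min": int(lengths.min()),
        "len_max": int(lengths.max()),
        "len_mean_floor": int(np.floor(lengths.mean())),
        "mfe_min": float(mfes.min()),
        "mfe_max": float(mfes.max()),
        "mfe_mean": round_half_up(float(mfes.mean()), 2),
    }
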