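"""Shared fixtures: one fully processed synthetic dataset per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from srnakit.annotate import annotate_tags
from srnakit.mapping import build_index, map_all
from srnakit.reads import collapse, trim_and_filter
from srnakit.synthetic import (SyntheticConfig, bundled_mature_mirnas, make_genome,
                               make_libraries)


@dataclass
class Dataset:
    config: SyntheticConfig
    genome: dict
    truth: object
    genes: list
    refs: list
    repeats: list
    reads: dict
    assignment: object
    tags: list
    hits: dict
    calls: dict
    index: object


def build_dataset(seed: int = 1, **overrides) -> Dataset:
    cfg = SyntheticConfig(seed=seed, **overrides)
    genome, truth, genes, refs, repeats = make_genome(cfg)
    reads, assignment = make_libraries(genome, truth, cfg)
    clean = {lib: trim_and_filter(r, cfg.adapter3, cfg.adapter5)[0] for lib, r in reads.items()}
    tags = collapse(clean)
    index = build_index(genome)
    hits = map_all(tags, index)
    calls = annotate_tags(tags, refs, bundled_mature_mirnas(), genes, hits)
    return Dataset(cfg, genome, truth, genes, refs, repeats, reads, assignment,
                   tags, hits, calls, index)


@pytest.fixture(scope="session")
def dataset() -> Dataset:
    return build_dataset(seed=1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260901)
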