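"""In-memory pipeline orchestration (the library counterpart of the CLI).

`run_pipeline` chains simulate -> trim -> collapse -> map -> annotate ->
discover on one configuration and returns every intermediate product;
`planted_recovery` scores one such run against the generator's truth
table (how many planted miRNA loci were called, and how many calls fall
outside any planted locus)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import annotate_tags, find_sirna_pairs
from .discovery import DiscoveryResult, discover, select_candidates
from .mapping import build_index, map_all
from .reads import collapse, trim_and_filter
from .synthetic import SyntheticConfig, bundled_mature_mirnas, make_genome, make_libraries


@dataclass
class PipelineRun:
    config: SyntheticConfig
    genome: dict
    truth: object
    genes: list
    refs: list
    repeats: list
    assignment: object
    trim_stats: dict
    tags: list
    hits: dict
    calls: dict
    discovery: DiscoveryResult


def run_pipeline(config: SyntheticConfig, n_shuffles: int = 199) -> PipelineRun:
    genome, truth, genes, refs, repeats = make_genome(config)
    reads, assignment = make_libraries(genome, truth, config)
    clean, stats = {}, {}
    for lib, lib_reads in reads.items():
        clean[lib], stats[lib] = trim_and_filter(lib_reads, config.adapter3, config.adapter5)
    tags = collapse(clean)
    index = build_index(genome)
    hits = map_all(tags, index)
    calls = annotate_tags(tags, refs, bundled_mature_mirnas(), genes, hits)
    non_annotated = [t for t in tags if calls[t.sequence].category == "non_annotated"]
    candidates = select_candidates(non_annotated, hits)
    result = discover(
        tags, candidates, hits, genome, list(config.library_ids),
        n_shuffles=n_shuffles, rng=np.random.default_rng([config.seed, 77]),
    )
    return PipelineRun(config, genome, truth, genes, refs, repeats, assignment,
                       stats, tags, hits, calls, result)


def planted_recovery(seed: int, five_prime_jitter: float = 0.2,
                     **overrides) -> tuple[int, int, int]:
    """(planted, recovered, false_accepts) for one simulated study.

    A call counts as a recovery when its precursor locus overlaps a
    planted hairpin (calls from the star arm of a planted hairpin are
    recoveries of that locus, not false positives); any accepted call
    outside every planted locus is a false accept."""
    cfg = SyntheticConfig(seed=seed, five_prime_jitter=five_prime_jitter, **overrides)
    run = run_pipeline(cfg)
    planted = run.truth.by_kind("hairpin")
    recovered: set[str] = set()
    false_accepts = 0
    for rep in run.discovery.accepted:
        chrom, s, e, strand = rep.location.split(":")
        s, e = int(s) - 1, int(e)
        matched = [p.name for p in planted
                   if p.chrom == chrom and not (e <= p.start or p.end <= s)]
        if matched:
            recovered.update(matched)
        else:
            false_accepts += 1
    return len(planted), len(recovered), false_accepts
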