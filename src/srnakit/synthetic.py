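"""Toy-genome simulator with planted, truth-annotated small-RNA features.

The generator builds an i.i.d.-uniform background genome and overwrites
it with non-overlapping planted features: miRNA-style hairpin loci
(constructed arm + loop + reverse-complement arm, so the precursor
criteria hold by construction), copies of bundled ncRNA and mature-miRNA
references, two-exon gene models, complementary siRNA pairs with 2-nt 3'
overhangs, a multi-copy repeat, an inverted-repeat pair, and a read
hot-spot. Three libraries are then simulated (analogues of a normal, a
nitrogen-limited and a silicon-limited culture): adapter-flanked 18-28 nt
inserts with negative-binomial redundant counts, optional 5'-end jitter
at mature loci, and a per-read ground-truth assignment table.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GeneModel, RefSeq, read_fasta_refs
from .sequences import random_dna, revcomp, validate_dna

LIBRARY_IDS = ("PT1", "PT2", "PT3")

# mismatch substitute: maps a base to one that neither Watson-Crick pairs
# nor G:U-wobbles with its partner's complement
_MISMATCH = {"A": "C", "C": "A", "G": "A", "T": "C"}


class SizingError(ValueError):
    """Raised when a chromosome cannot host a requested feature."""


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 5000
    n_hairpin_loci: int = 4
    mature_len_range: tuple[int, int] = (20, 23)
    stem_pairs_range: tuple[int, int] = (20, 25)
    stem_mismatches_range: tuple[int, int] = (0, 2)
    n_ncrna_loci: dict[str, int] = field(
        default_factory=lambda: {"rRNA": 2, "tRNA": 2, "snRNA": 1, "snoRNA": 1, "known_miRNA": 2}
    )
    n_gene_models: int = 3
    n_sirna_pairs: int = 3
    n_repeat_copies: int = 2
    inverted_repeat: bool = True
    hotspot: bool = True
    hotspot_len: int = 1200
    # per-library read-count model (negative binomial: mean, dispersion k;
    # smaller k = heavier tail). Background defaults reproduce the
    # "sequenced once" majority seen in deep small-RNA libraries.
    feature_mean_reads: float = 20.0
    feature_dispersion: float = 5.0
    background_mean_reads: float = 4.0  # per background locus
    background_dispersion: float = 0.8
    n_background_loci: int = 8
    hotspot_reads: int = 60
    five_prime_jitter: float = 0.1
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    read_length: int = 36
    library_ids: tuple[str, ...] = LIBRARY_IDS

    def validate(self) -> "SyntheticConfig":
        counts = [
            self.n_chromosomes, self.chrom_length, self.n_hairpin_loci,
            self.n_gene_models, self.n_sirna_pairs, self.n_repeat_copies,
            self.n_background_loci, self.hotspot_reads,
            *self.n_ncrna_loci.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all feature counts must be >= 0")
        if not 0.0 <= self.five_prime_jitter <= 1.0:
            raise ValueError("five_prime_jitter must lie in [0, 1]")
        lo, hi = self.mature_len_range
        if not (18 <= lo <= hi <= 25):
            raise ValueError("mature_len_range must lie within [18, 25]")
        if not self.adapter3:
            raise ValueError("adapter3 must be a non-empty sequence")
        validate_dna(self.adapter3)
        if self.adapter5:
            validate_dna(self.adapter5)
        return self


@dataclass
class TruthRecord:
    kind: str  # hairpin | rRNA | tRNA | snRNA | snoRNA | known_miRNA | exon |
    #            intron | siRNA_pair | repeat | inverted_repeat | hotspot
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    payload: str  # genome substring, reverse-complemented on the minus strand
    category: str  # expected annotation category for reads from this feature
    name: str = ""
    attrs: dict = field(default_factory=dict)


class TruthTable:
    def __init__(self, records: list[TruthRecord] | None = None):
        self.records: list[TruthRecord] = records or []

    def add(self, rec: TruthRecord) -> None:
        self.records.append(rec)

    def by_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": r.kind, "name": r.name, "chrom": r.chrom, "strand": r.strand,
                    "start": r.start, "end": r.end, "payload": r.payload,
                    "category": r.category, "attrs": json.dumps(r.attrs, sort_keys=True),
                }
                for r in self.records
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        recs = [
            TruthRecord(
                row["kind"], row["chrom"], row["strand"], int(row["start"]), int(row["end"]),
                row["payload"], row["category"], row["name"],
                json.loads(row["attrs"]) if isinstance(row["attrs"], str) else {},
            )
            for _, row in df.iterrows()
        ]
        return cls(recs)


def bundled_ncrna_refs() -> list[RefSeq]:
    """Miniature ncRNA reference set shipped with the package.

    These records are synthetic stand-ins constructed for offline testing;
    they are labelled with the class and source fields the annotation
    priority rule needs (GenBank outranks Rfam)."""
    path = importlib.resources.files("srnakit.data") / "synthetic_ncrna_refs.fasta"
    return read_fasta_refs(str(path))


def bundled_mature_mirnas() -> list[RefSeq]:
    """Miniature synthetic mature-miRNA set (miRBase-style stand-ins)."""
    path = importlib.resources.files("srnakit.data") / "synthetic_mature_mirnas.fasta"
    return read_fasta_refs(str(path))


class _Placer:
    """Tracks occupied intervals and places features without overlap."""

    MARGIN = 25

    def __init__(self, rng: np.random.Generator, chrom_names: list[str], chrom_length: int):
        self.rng = rng
        self.chrom_names = chrom_names
        self.chrom_length = chrom_length
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place(self, length: int, feature_name: str, chrom: str | None = None) -> tuple[str, int]:
        if length + 2 * self.MARGIN > self.chrom_length:
            raise SizingError(
                f"chromosome length {self.chrom_length} too short for feature {feature_name!r} "
                f"of length {length}"
            )
        for _ in range(300):
            c = chrom if chrom is not None else str(self.rng.choice(self.chrom_names))
            start = int(self.rng.integers(self.MARGIN, self.chrom_length - length - self.MARGIN))
            if all(start >= e + self.MARGIN or start + length + self.MARGIN <= s
                   for s, e in self.occupied[c]):
                self.occupied[c].append((start, start + length))
                return c, start
        raise SizingError(f"could not place feature {feature_name!r} of length {length}")


def _build_hairpin(rng: np.random.Generator, cfg: SyntheticConfig) -> tuple[str, int, int, int]:
    """Return (hairpin sequence, mature_offset, mature_len, stem_len).

    The mature sits at the very 5' end of the 5' arm; symmetric mismatches
    are injected into the 3' arm, never so many that fewer than 16 mature
    bases stay paired."""
    m = int(rng.integers(cfg.mature_len_range[0], cfg.mature_len_range[1] + 1))
    s = int(rng.integers(max(cfg.stem_pairs_range[0], m), cfg.stem_pairs_range[1] + 1))
    n_mm = int(rng.integers(cfg.stem_mismatches_range[0], cfg.stem_mismatches_range[1] + 1))
    arm = random_dna(rng, s)
    loop = random_dna(rng, int(rng.integers(8, 13)))
    star = list(revcomp(arm))
    allowed_in_mature = max(0, m - 16)
    # mismatches go to the stem interior (>= 6 bp from either helix end,
    # pairwise separation >= 4) so the planted duplex cannot fray at the
    # termini; this is what guarantees the hairpin criteria by construction
    pool = list(range(6, s - 6))
    rng.shuffle(pool)
    placed: list[int] = []
    in_mature = 0
    for pos in pool:
        if len(placed) >= n_mm:
            break
        if pos < m and in_mature >= allowed_in_mature:
            continue
        if any(abs(pos - q) < 4 for q in placed):
            continue
        # star index pairing with arm position pos is s-1-pos
        star[s - 1 - pos] = _MISMATCH[arm[pos]]
        placed.append(pos)
        if pos < m:
            in_mature += 1
    return arm + loop + "".join(star), 0, m, s


def _nb_count(rng: np.random.Generator, mean: float, k: float) -> int:
    """Negative-binomial draw (mean, dispersion k), floored at 1."""
    p = k / (k + mean)
    return max(1, int(rng.negative_binomial(k, p)))


def make_genome(config: SyntheticConfig):
    """Build the toy genome and all companion annotation inputs.

    Returns (genome dict name->seq, TruthTable, gene models, ncRNA refs,
    repeat intervals)."""
    cfg = config.validate()
    rng = np.random.default_rng([cfg.seed, 101])
    chrom_names = [f"chr_{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_arrays = {c: list(random_dna(rng, cfg.chrom_length)) for c in chrom_names}
    placer = _Placer(rng, chrom_names, cfg.chrom_length)
    truth = TruthTable()
    ncrna_refs = bundled_ncrna_refs()
    mature_refs = bundled_mature_mirnas()
    repeats: list[tuple[str, int, int, str]] = []
    genes: list[GeneModel] = []

    def plant(seq: str, kind: str, category: str, name: str, strand: str = "+",
              attrs: dict | None = None, chrom: str | None = None) -> TruthRecord:
        c, start = placer.place(len(seq), name, chrom=chrom)
        genome_seq = seq if strand == "+" else revcomp(seq)
        chrom_arrays[c][start:start + len(seq)] = list(genome_seq)
        rec = TruthRecord(kind, c, strand, start, start + len(seq), seq, category, name, attrs or {})
        truth.add(rec)
        return rec

    by_class: dict[str, list[RefSeq]] = {}
    for ref in ncrna_refs:
        by_class.setdefault(ref.rclass, []).append(ref)

    # large features are planted first so they can still find room
    # hot spot: a tandem rRNA-repeat window that will receive a
    # disproportionate read share (rRNA loci dominate real libraries, so
    # hot-spot reads are annotated away before miRNA discovery)
    if cfg.hotspot:
        unit = by_class["rRNA"][0]
        n_copies = max(1, cfg.hotspot_len // len(unit.sequence))
        hs = unit.sequence * n_copies
        plant(hs, "hotspot", "hotspot", "hotspot_1", "-",
              {"unit_len": len(unit.sequence), "n_copies": n_copies})

    # inverted repeat pair: second copy is the exact reverse complement
    if cfg.inverted_repeat:
        ir = random_dna(rng, 400)
        plant(ir, "inverted_repeat", "inverted_repeat", "IRa", "+")
        plant(revcomp(ir), "inverted_repeat", "inverted_repeat", "IRb", "+")

    # gene models: exon - intron - exon
    for g in range(cfg.n_gene_models):
        e1, intr, e2 = 200, 120, 200
        seq = random_dna(rng, e1 + intr + e2)
        strand = "+" if rng.random() < 0.5 else "-"
        rec = plant(seq, "gene", "gene", f"gene_{g + 1}", strand)
        s = rec.start
        exons = [(s, s + e1), (s + e1 + intr, s + e1 + intr + e2)]
        genes.append(GeneModel(f"gene_{g + 1}", rec.chrom, strand, exons))
        # truth intervals for exon/intron pieces (genomic coordinates;
        # payloads read 5'->3' on the transcript strand)
        def _piece(ps, pe):
            piece = "".join(chrom_arrays[rec.chrom][ps:pe])
            return piece if strand == "+" else revcomp(piece)

        for (es, ee) in exons:
            truth.add(TruthRecord("exon", rec.chrom, strand, es, ee,
                                  _piece(es, ee), "exon_sense", f"gene_{g + 1}_exon"))
        truth.add(TruthRecord("intron", rec.chrom, strand, s + e1, s + e1 + intr,
                              _piece(s + e1, s + e1 + intr),
                              "intron_sense", f"gene_{g + 1}_intron"))

    # repeat: one sequence copied n times
    if cfg.n_repeat_copies > 0:
        rep = random_dna(rng, 300)
        for k in range(cfg.n_repeat_copies):
            rec = plant(rep, "repeat", "repeat", f"repeat_c{k + 1}", "+")
            repeats.append((rec.chrom, rec.start, rec.end, f"repeat_c{k + 1}"))

    # ncRNA loci: copies of bundled references
    for rclass, n in cfg.n_ncrna_loci.items():
        if rclass == "known_miRNA":
            for k in range(n):
                ref = mature_refs[k % len(mature_refs)]
                strand = "+" if rng.random() < 0.5 else "-"
                plant(ref.sequence, "known_miRNA", "known_miRNA",
                      f"{ref.name}_locus{k + 1}", strand, {"ref": ref.name})
            continue
        pool_refs = by_class.get(rclass, [])
        for k in range(n):
            ref = pool_refs[k % len(pool_refs)]
            strand = "+" if rng.random() < 0.5 else "-"
            plant(ref.sequence, rclass, rclass, f"{ref.name}_locus{k + 1}", strand, {"ref": ref.name})

    # hairpin miRNA loci
    for h in range(cfg.n_hairpin_loci):
        hp, moff, mlen, stem = _build_hairpin(rng, cfg)
        strand = "+" if rng.random() < 0.5 else "-"
        plant(hp, "hairpin", "candidate_miRNA", f"hairpin_{h + 1}", strand,
              {"mature_offset": moff, "mature_len": mlen, "stem": stem})

    # siRNA pairs: a dsRNA window T of length L+2; guide = T[2:], passenger =
    # revcomp(T[:L+? ]) -- both strands end with a 2-nt 3' overhang
    for p in range(cfg.n_sirna_pairs):
        L = 21
        seq = random_dna(rng, L + 2)
        rec = plant(seq, "siRNA_pair", "siRNA", f"sirna_{p + 1}", "+")
        t = rec.payload
        tag_a = t[2:]                 # plus strand, 5' at rec.start+2
        tag_b = revcomp(t[:L])        # minus strand, 5' at rec.start+L-1
        truth.records[-1].attrs.update({"tag_a": tag_a, "tag_b": tag_b})

    genome = {c: "".join(chrom_arrays[c]) for c in chrom_names}
    return genome, truth, genes, ncrna_refs, repeats


def _read_from(genome: dict[str, str], chrom: str, strand: str, start: int, end: int) -> str:
    s = genome[chrom][start:end]
    return s if strand == "+" else revcomp(s)


def make_libraries(genome: dict[str, str], truth: TruthTable, config: SyntheticConfig):
    """Simulate the three libraries.

    Returns (reads dict lib -> list[(read_id, sequence)], assignment
    DataFrame with one row per emitted read template: library, source
    feature, tag sequence, count, 5'-shift flag)."""
    cfg = config.validate()
    rng = np.random.default_rng([cfg.seed, 202])
    libs = list(cfg.library_ids)
    reads: dict[str, list[tuple[str, str]]] = {lib: [] for lib in libs}
    rows = []
    counter = {lib: 0 for lib in libs}

    def emit(lib: str, tag: str, count: int, source: str, kind: str, shifted: bool = False):
        if count <= 0:
            return
        for _ in range(count):
            counter[lib] += 1
            rid = f"{lib}_r{counter[lib]}"
            full = tag + cfg.adapter3
            read = full[: cfg.read_length]
            if len(read) < cfg.read_length:
                read = read + cfg.adapter3[: cfg.read_length - len(read)]
            reads[lib].append((rid, read))
        rows.append({"library": lib, "source": source, "kind": kind, "tag": tag,
                     "count": count, "shifted": shifted})

    def lib_subset() -> list[str]:
        chosen = [lib for lib in libs if rng.random() < 0.7]
        return chosen or [str(rng.choice(libs))]

    # mature miRNA reads from planted hairpins (plus occasional star reads)
    for rec in truth.by_kind("hairpin"):
        moff, mlen, stem = rec.attrs["mature_offset"], rec.attrs["mature_len"], rec.attrs["stem"]
        if rec.strand == "+":
            mstart, mend = rec.start + moff, rec.start + moff + mlen
        else:
            mend = rec.end - moff
            mstart = mend - mlen
        star_len = mlen
        hp_len = rec.end - rec.start
        for lib in lib_subset():
            n = _nb_count(rng, cfg.feature_mean_reads, cfg.feature_dispersion)
            n_shift = int(rng.binomial(n, cfg.five_prime_jitter))
            emit(lib, _read_from(genome, rec.chrom, rec.strand, mstart, mend),
                 n - n_shift, rec.name, "hairpin", shifted=False)
            for _ in range(n_shift):
                off = int(rng.choice([-1, 1]))
                if rec.strand == "+":
                    s2, e2 = mstart + off, mend + off
                else:
                    s2, e2 = mstart - off, mend - off
                emit(lib, _read_from(genome, rec.chrom, rec.strand, s2, e2),
                     1, rec.name, "hairpin", shifted=True)
            # star arm reads (3' arm of the same transcript, same genomic strand)
            if rng.random() < 0.5:
                if rec.strand == "+":
                    ss, se = rec.end - star_len, rec.end
                else:
                    ss, se = rec.start, rec.start + star_len
                emit(lib, _read_from(genome, rec.chrom, rec.strand, ss, se),
                     _nb_count(rng, 1.5, 1.0), rec.name, "hairpin_star")

    # degradation fragments from ncRNA loci, exons and introns
    for kind in ("rRNA", "tRNA", "snRNA", "snoRNA", "exon", "intron"):
        for rec in truth.by_kind(kind):
            for lib in lib_subset():
                for _ in range(int(rng.integers(1, 4))):
                    flen = int(rng.integers(18, 29))
                    if rec.end - rec.start < flen:
                        continue
                    fs = int(rng.integers(rec.start, rec.end - flen + 1))
                    strand = rec.strand
                    if kind in ("exon", "intron") and rng.random() < 0.15:
                        strand = "-" if strand == "+" else "+"  # antisense fragment
                    emit(lib, _read_from(genome, rec.chrom, strand, fs, fs + flen),
                         _nb_count(rng, cfg.feature_mean_reads / 4, cfg.feature_dispersion),
                         rec.name, kind)

    # known miRNA loci: reads are the mature sequence itself
    for rec in truth.by_kind("known_miRNA"):
        for lib in lib_subset():
            emit(lib, rec.payload, _nb_count(rng, cfg.feature_mean_reads / 2,
                                             cfg.feature_dispersion), rec.name, "known_miRNA")

    # siRNA duplex pairs: both strands emitted
    for rec in truth.by_kind("siRNA_pair"):
        for lib in lib_subset():
            emit(lib, rec.attrs["tag_a"], _nb_count(rng, 3.0, 2.0), rec.name, "siRNA_pair")
            emit(lib, rec.attrs["tag_b"], _nb_count(rng, 3.0, 2.0), rec.name, "siRNA_pair")

    # hot-spot reads: many fragments from the hotspot window on its strand
    for rec in truth.by_kind("hotspot"):
        unit = rec.attrs["unit_len"]
        for lib in libs:
            for _ in range(cfg.hotspot_reads):
                flen = int(rng.integers(18, 29))
                copy = int(rng.integers(0, rec.attrs["n_copies"]))
                off = int(rng.integers(0, unit - flen + 1))
                fs = rec.start + copy * unit + off
                emit(lib, _read_from(genome, rec.chrom, rec.strand, fs, fs + flen),
                     _nb_count(rng, 4.0, 1.0), rec.name, "hotspot")

    # random genomic background: each locus sheds overlapping fragments
    # whose 5' ends scatter independently per read (degradation-style
    # raggedness, the property the 5'-homogeneity rule discriminates on);
    # identical reads arise only by offset/length collision, so unique
    # background tags are overwhelmingly singletons
    chroms = list(genome)
    for lib in libs:
        for b in range(cfg.n_background_loci):
            c = str(rng.choice(chroms))
            anchor = int(rng.integers(0, len(genome[c]) - 60))
            strand = "+" if rng.random() < 0.5 else "-"
            n_reads = _nb_count(rng, cfg.background_mean_reads, cfg.background_dispersion)
            frags: dict[tuple[int, int], int] = {}
            for _ in range(n_reads):
                off = int(rng.integers(0, 12))
                flen = int(rng.integers(18, 29))
                frags[(off, flen)] = frags.get((off, flen), 0) + 1
            for (off, flen), count in sorted(frags.items()):
                fs = anchor + off
                emit(lib, _read_from(genome, c, strand, fs, fs + flen),
                     count, f"background_{lib}_{b}", "background")

    # artifacts: unligated reads (no adapter) and one N-containing read
    for lib in libs:
        for _ in range(3):
            counter[lib] += 1
            reads[lib].append((f"{lib}_r{counter[lib]}", random_dna(rng, cfg.read_length)))
        counter[lib] += 1
        junk = random_dna(rng, 20) + "N" + cfg.adapter3
        reads[lib].append((f"{lib}_r{counter[lib]}", junk[: cfg.read_length]))

    assignment = pd.DataFrame(rows)
    return reads, assignment


def simulate(config: SyntheticConfig):
    """Convenience wrapper: genome + libraries in one call."""
    genome, truth, genes, refs, repeats = make_genome(config)
    reads, assignment = make_libraries(genome, truth, config)
    return genome, truth, genes, refs, repeats, reads, assignment


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
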