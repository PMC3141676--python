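"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; GFF3 is written directly (1-based
inclusive, per the format spec) and read back with gffutils; BED is
0-based half-open; report tables are TSV with ``#``-prefixed provenance
headers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneModel:
    """A transcript with exon intervals (0-based half-open, sorted)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
            if self.exons[k + 1][0] > self.exons[k][1]
        ]


@dataclass(frozen=True)
class RefSeq:
    """A labelled reference sequence (e.g. an rRNA fragment or mature miRNA)."""

    name: str
    sequence: str
    rclass: str = ""  # rRNA | tRNA | snRNA | snoRNA | miRNA
    source: str = ""  # genbank | rfam | mirbase


def write_fasta(path: str | os.PathLike, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.description or rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fasta_refs(path: str | os.PathLike) -> list[RefSeq]:
    """Read a labelled reference FASTA; class/source parsed from key=value
    tokens in the description (``class=rRNA source=genbank``)."""
    refs = []
    for desc, seq in read_fasta(path):
        fields = desc.split()
        name = fields[0]
        kv = dict(tok.split("=", 1) for tok in fields[1:] if "=" in tok)
        refs.append(RefSeq(name, seq, kv.get("class", ""), kv.get("source", "")))
    return refs


def write_fastq(path: str | os.PathLike, reads: list[tuple[str, str]], quality_char: str = "I") -> None:
    """Write reads as (id, sequence) with a constant phred33 quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Return (id, sequence, quality-string) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)))
    return out


def write_collapsed_fasta(path: str | os.PathLike, tags: list[tuple[str, int]], prefix: str = "tag") -> None:
    """Collapsed-FASTA dialect: headers ``>tagN_xCOUNT``."""
    with open(path, "w") as fh:
        for n, (seq, count) in enumerate(tags, start=1):
            fh.write(f">{prefix}{n}_x{count}\n{seq}\n")


def read_collapsed_fasta(path: str | os.PathLike) -> list[tuple[str, int]]:
    out = []
    for desc, seq in read_fasta(path):
        count = int(desc.split("_x")[-1])
        out.append((seq, count))
    return out


def write_gff3(path: str | os.PathLike, genes: list[GeneModel], extra_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in extra_comments or []:
            fh.write(f"# {line}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsrnakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsrnakit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tsrnakit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.t1.exon{k};Parent={g.gene_id}.t1\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted((e.start - 1, e.end) for e in db.children(mrna, featuretype="exon"))
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        genes.append(GeneModel(gene_id, mrna.seqid, mrna.strand, exons))
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_bed(path: str | os.PathLike, intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


def write_table(df: pd.DataFrame, path: str | os.PathLike, comments: list[str] | None = None) -> None:
    """TSV writer with ``#`` provenance header lines."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
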