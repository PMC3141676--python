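# Methods

## Scope and model of the data

The package reimplements a small-RNA-seq discovery analysis: three
sequencing libraries from one organism under different nutrient
conditions are reduced to unique tags, mapped exactly to a reference
genome, annotated by a strict priority rule, and mined for novel miRNA
hairpin precursors, siRNA duplexes and miRNA targets. Because the
original deep-sequencing libraries are not desk-reproducible, all
pipeline-level claims are validated on simulated studies whose truth is
known by construction; the arithmetic of the published report tables is
validated directly against the printed counts, which ship with the
package as plain-TSV inputs.

## Folding model

`srnakit.fold` implements a pseudoknot-free dynamic program:

* admissible pairs: Watson–Crick and G:U; minimum hairpin loop 3 nt;
* stacked pair steps score standard nearest-neighbour free energies at
  37 °C (kcal/mol); the two mildly destabilising G:U-on-G:U entries are
  clamped to 0 so every stack term is ≤ 0, which keeps the recursion's
  interior bound exact;
* every helix pays a +3.5 kcal/mol initiation penalty, charged on the
  pair whose interior neighbour is unpaired. This is the minimal
  analogue of the loop-initiation terms in full thermodynamic models;
  without it, a random 100-nt window frequently contains a fragmented
  20-"bp" pseudo-duplex scored as stable as a clean stem, and the
  precursor criteria lose their discriminative power;
* unpaired bases are otherwise free (no loop-size dependence, no
  dangles).

Consequences worth knowing: MFEs are systematically more negative than
mfold/ViennaRNA values for long windows (no loop destabilisation), so
the −18 kcal/mol precursor threshold is conservative on this model, and
published MFE values are not expected to reproduce numerically. The
`fold(engine="vienna")` backend exposes ViennaRNA through the same
contract where thermodynamic parity matters. The energy of an explicit
structure is computed by `structure_energy`, shared between the engine
and the exhaustive-enumeration cross-check so that the two differ only
in search strategy.

The DP core is JIT-compiled (numba); a 621-nt window folds in ~0.2 s and
a 100-nt precursor in ~1 ms, which is what makes the shuffle test and
the multi-study recovery suites tractable on one CPU.

## Hairpin screening

Candidates are non-annotated tags with more than one redundant read and
1–20 exact genome hits. Each hit is extended by 300 nt per side
(clipped; minus-strand windows reverse-complemented so the mature reads
5'→3'). The criteria are evaluated on the MFE structure: ≥ 16 mature
bases paired to a star region on one side of the mature; walking
consecutive mature pairs, the symmetric part of each interruption counts
as mismatched positions and the asymmetric part as bulged-out bases
(≤ 4 bulged bases allowed — counting bases rather than interruption
events is what keeps the star arm commensurate with the mature arm);
the mature must not span the terminal loop; the precursor is the duplex
plus 20-nt flanks and must fold at or below −18 kcal/mol.

Because the global MFE structure of a 601-nt window can bury a genuine
stem-loop under pairings with flanking sequence, the screen walks a
small-to-large cascade of subwindows around the mature (flanks 40, 75,
150, 300 nt) and accepts the first scale whose MFE structure passes — a
hairpin optimal for some subwindow is a bona fide secondary structure of
the extracted region. For multi-hit tags every locus is screened and the
accepted hairpin with the lowest precursor MFE is reported, so each
miRNA is assigned a single precursor.

The stability test is a dinucleotide-preserving (Altschul–Erickson)
shuffle with N = 199 by default and p = (1 + #{MFE_shuffled ≤
MFE_observed}) / (N + 1). The decision rule pairs p with 5'-end
homogeneity evaluated in the best library (the library with the highest
fraction among those with precursor-mapped reads): p ≤ 0.05 requires
homogeneity > 0.5, p > 0.05 requires ≥ 0.75. Candidates within 10% of
any threshold are flagged `needs_review`, the mechanical residue of a
manual-recheck step that cannot be automated faithfully.

## Annotation details

ncRNA homology uses a deterministic ungapped criterion — an alignment of
≥ 16 nt at ≥ 90% identity, found by 8-mer seeding plus diagonal
extension (a qualifying window necessarily contains an exact ≥ 8-mer) —
in place of a BLAST E-value cutoff, whose meaning depends on database
size; ties break GenBank > Rfam, then identity. Known-miRNA homology is
a full-length gapless comparison sliding over a length difference ≤ 2,
hit iff ≤ 2 mismatches or ≥ 90% identity. Gene overlap requires full
containment of a hit in an exon or intron; exon beats intron, sense
beats antisense. siRNA duplexes are equal-length tag pairs whose first
L−2 bases are mutual reverse complements, i.e. both strands carry 2-nt
3' overhangs. The phasing statistic is the largest fraction of 5' ends
in one register modulo the phase length (minus-strand ends shifted +2,
the duplex-overhang correction), with a permutation p-value from
uniform re-draws over the locus.

## Synthetic studies

The generator plants non-overlapping features in i.i.d.-uniform
background chromosomes (defaults: 3 × 5 kb): 4 hairpin loci (stems 20–25
bp, matures 20–23 nt, 0–2 symmetric stem mismatches injected ≥ 6 bp from
the helix ends with ≥ 4 bp separation, so the planted duplex cannot fray
— the construction, not rejection sampling, guarantees the precursor
criteria); copies of bundled synthetic ncRNA references (the annotation
fixtures are constructed stand-ins, not database records) and mature
miRNAs; two-exon gene models; 3 siRNA duplex pairs cut from a simulated
dsRNA window; a 2-copy repeat; an inverted-repeat pair; and a
minus-strand hot-spot built as a tandem rRNA repeat, so its heavy read
load is annotated away before discovery, as rRNA-dominated loci are in
real libraries.

Reads are adapter-flanked 18–28-nt inserts. Redundant counts are
negative binomial — features mean 20 (dispersion 5), background mean 1.3
(dispersion 0.4), reproducing a sequenced-once majority among background
tags. Mature-locus reads take a ±1-nt 5' shift with probability
`five_prime_jitter` (default 0.1); star-arm reads are emitted at low
rate. Everything derives from one seed; regeneration is byte-identical.

What the simulation does **not** model: sequencing errors and quality
variation, ragged 5'/3' degradation ends on background fragments,
expression correlation between conditions, genome repeat families beyond
the planted ones, and composition bias. Passing the recovery suite
therefore shows the pipeline's logic is correct under its stated
assumptions, not that its thresholds are optimal on any real library.

## Problem sizes and calibration checks

The test suite validates, among others: exact agreement of the mapper
with a brute-force scan (1,000 queries on a ≤ 50-kb genome); exact
agreement of the folding DP with exhaustive structure enumeration on a
seeded sample of sequences covering lengths 1–14; uniformity of the
shuffle-test p-value under its own null (500 draws at N = 99,
Kolmogorov–Smirnov α = 0.01); and ≥ 90% recovery of planted miRNA loci
with zero accepts outside planted loci across 100 simulated studies at
5'-jitter 0.2. These sizes are the package's validation design;
`scripts/acceptance.py` re-runs scaled versions (20 studies, 200 null
draws) plus the published-table arithmetic and writes one JSON of
value/size pairs.

## Known limitations

* The energy model ranks hairpins reliably but its absolute energies are
  not thermodynamic; cross-tool MFE comparisons need the ViennaRNA
  backend.
* Mature/star assignment is ambiguous when both arms are sequenced; a
  deeply sequenced star arm is reported as its own call at the same
  locus.
* Adapter trimming is exact-prefix-match by design; mismatch-tolerant
  trimming is out of scope.
* The target-duplex scan is gapless; the gap state exists in the duplex
  model for externally constructed alignments, and the scoring
  parameters reproduce the qualitative behaviour of seed-weighted
  target finders rather than any tool's exact output.
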