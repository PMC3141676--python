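# srnakit

Small-RNA sequencing analysis for organisms without a miRNA catalogue —
from raw reads to annotated tag categories, novel miRNA calls, siRNA
duplexes and predicted targets — packaged with a synthetic-data
generator that plants ground-truth features in a toy genome so every
stage is testable offline.

The design follows the analysis used to discover the first microRNAs of
the diatom *Phaeodactylum tricornutum* from three deep-sequenced
small-RNA libraries (normal, nitrogen-limited and silicon-limited
cultures, here PT1–PT3).

## What the pipeline does

1. **Read processing** — 3'-adapter trimming (exact match of the
   adapter's first 8 nt), quality/length filtering (18–30 nt kept), and
   collapsing into unique *tags* with per-library redundant counts.
2. **Mapping** — exact-match, all-hits, both-strand placement on the
   genome (no mismatches), plus per-chromosome strand profiles and
   sliding-window hot-spot extraction.
3. **Annotation** — each tag gets exactly one category through the
   priority chain
   `rRNA/tRNA/snRNA/snoRNA (GenBank > Rfam) > known miRNA > exon >
   intron > siRNA > non-annotated`.
   siRNA duplexes are pairs of perfectly complementary tags with 2-nt 3'
   overhangs; phasing of siRNA 5' ends is scored with a register
   statistic and permutation p-value.
4. **miRNA discovery** — non-annotated tags with more than one read and
   at most 20 genome hits are extended by 300 nt on each side, folded,
   and screened with the hairpin precursor criteria: precursor MFE ≤ −18
   kcal/mol, ≥ 16 base pairs between the mature and star arms, ≤ 4
   bulged-out bases, mature length 18–25 nt, 20-nt retained flank.
   Stability is tested by dinucleotide shuffling
   (p = (1 + #{shuffled MFE ≤ observed}) / (N + 1), N = 199), and the
   final call combines p with 5'-end homogeneity (the fraction of
   precursor-mapped reads sharing the mature 5' end):
   accept iff (p ≤ 0.05 and homogeneity > 0.5) or
   (p > 0.05 and homogeneity ≥ 0.75).
5. **Target prediction** — duplex scan with seed weighting (miRNA
   positions 2–8 scaled ×2, score ≥ 90, duplex ΔG ≤ −20 kcal/mol)
   followed by position-specific rules counted from the miRNA 5' end
   (G:U wobble = 0.5 mismatches): ≤ 4 mismatches at 2–21, no run of > 2
   adjacent mismatches, none adjacent at 2–12, strict Watson–Crick at
   10–11, ≤ 2.5 weighted at 1–12, and duplex MFE > 74% of the MFE
   against the miRNA's perfect complement. A relaxed variant enforces
   only the positions-2–21 budget.

Folding uses an in-package nested-structure dynamic program over
nearest-neighbour stacking energies (Watson–Crick + G:U, minimum loop 3,
helix-initiation penalty); ViennaRNA can be plugged in through the same
interface. See `docs/methods.md` for the model and its limits.

## Worked example

```
srnakit --seed 5 --outdir run5 all
```

simulates three libraries from a 3×5-kb toy genome with 4 planted
hairpin loci, then runs every stage. On this seed the log reports

```
collapsed to 355 unique tags
mapped 355/355 tags
annotated 355 tags (3 siRNA duplex pairs)
12 candidates -> 4 accepted miRNAs
```

and `run5/mirna_report.tsv` contains one row per accepted precursor,
e.g.

```
name             location           mfe    len  P-value  PT1     PT2     PT3     bulges  mismatched
candidate-miR-1  chr_2:1407:1488:+  -30.9  82   0.01     16/16   26/27   22/25   0       2
```

Read it as: a precursor at that locus, −30.9 kcal/mol over 82 nt,
dinucleotide-shuffle p = 0.01, and in PT2 26 of the 27 reads mapped to
the precursor share the mature 5' end (homogeneity 0.96; the rule needs
> 0.5 at this p). The 3 detected siRNA duplex pairs and the minus-strand
hot-spot in `hotspots.tsv` correspond to the planted truth in
`truth.tsv`. A call can sit on either strand of a planted hairpin —
mature/star assignment is a known ambiguity of hairpin-based discovery.

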