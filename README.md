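# parclip

Analysis pipeline for PAR-CLIP data from RNA-binding proteins, built around
the Nrd1–Nab3 transcription-termination system in budding yeast, together
with a ground-truth simulator so every stage can be validated without
external data.

In PAR-CLIP, 4-thiouridine incorporated into nascent RNA cross-links to a
bound protein under UV and leaves a diagnostic **T→C transition** in the
sequenced cDNA at the contact site. Given aligned reads, the analytical
problem is to decide which read pile-ups are signal rather than expression
bias, which sequence motifs the protein binds, and where within transcript
architecture (5′UTR / CDS / 3′UTR) binding concentrates. This package is
for computational biologists who want those steps as a tested, seedable
library and CLI rather than a collection of one-off scripts.

## What it computes

- **Duplicate collapsing and unique alignment.** Exact-duplicate reads are
  collapsed (PCR duplicates); a substitution-only exhaustive matcher keeps a
  read only if exactly one placement over both strands attains the minimum
  mismatch count (≤ 2 by default). Pre-aligned SAM/BED input is accepted too.
- **Randomization FDR per feature.** With no control library, the
  significance of a coverage height *h* inside a gene is assessed by
  re-placing the gene's reads uniformly at random *n*<sub>iter</sub> = 100
  times:

  FDR(*h*) = E[#positions with randomized coverage ≥ *h*] / #positions with
  observed coverage ≥ *h*, capped at 1.

  The smallest *h* with (monotone-cleaned) FDR ≤ α = 0.01 is the feature's
  minimum significant height; maximal runs of positions at or above it are
  the selected intervals.
- **Contigs with per-position T-C counts.** Each selected interval carries
  coverage, T→C substitution counts (A→G on the − strand) and covered-T
  counts per position.
- **Motif analysis.** k-mer (4–6 nt) over-representation in contigs is
  scored as *z* = (obs − mean<sub>shuffled</sub>)/sd<sub>shuffled</sub>
  against per-contig composition-preserving shuffles, with each k-mer counted
  at most once per contig. Exact motif occurrences (Nab3 UCUU/CUUG, Nrd1
  UGUA/GUAG by default) are scanned genome-wide; occurrences inside contigs
  supported by ≥ 1 T-C substitution are **cross-linked motifs**.
- **Profiles.** Length-normalized metagene profiles (10 + 130 + 10 bins over
  5′UTR/CDS/3′UTR), per-bin binding probability (cross-linked density ÷
  all-motif density), anchor windows around TSS/stop codon/poly(A) site
  (±500 nt), T-C percentage profiles around motifs (±50 nt), per-gene bin
  matrices and seeded k-means row clustering.
- **Summaries.** Per-class motif/cross-linked percentages, 5′UTR/CDS/3′UTR
  assignment of cross-linked motifs, stop-codon overlap of Nrd1 motifs, and
  a two-sample Kolmogorov–Smirnov comparison of target transcript lengths.

The simulator generates a random genome, an intronless annotation with UTRs
and real stop codons, planted motif sites with designated cross-link Ts, and
strand-specific reads with tunable conversion rate, error rate and PCR
duplication — all logged to a truth table for end-to-end scoring.

## Worked example

```bash
parclip -v run-all --outdir demo --seed 7
```

```
INFO parclip: simulating synthetic scenario (seed=7)
INFO parclip: collapsed 4374 raw reads to 3316 distinct sequences
INFO parclip: aligned 3316/3316 collapsed reads uniquely
INFO parclip: peak calling: 7 contigs across 7 features
INFO parclip: motifs: 1408 genome-wide, 16 in contigs, 9 cross-linked
done: 9 cross-linked motifs, 7 target transcripts
```

Reading this: 4,374 simulated reads collapse to 3,316 distinct cDNAs
(the difference is PCR duplication), all of which map uniquely on the 40 kb
synthetic genome. Seven features contain coverage heights that beat the
randomization null at FDR ≤ 0.01, yielding 7 contigs. Of 1,408 genome-wide
occurrences of the four Nrd1/Nab3 motifs, only 16 fall inside significant
contigs, and 9 of those carry a T→C substitution in an overlapping read —
the cross-linked motifs. The planted sites in this scenario sit in 7
transcripts, and `demo/target_table.tsv` recovers every one of them. The
region breakdown (`demo/region_distribution.tsv`):

```
utr5	cds	utr3	no_utr_fallback	unassigned
2	5	2	0	0
```

matches the planted geometry (2 sites per UTR class, 4 in CDS, one shared
transcript). All stage outputs are plain text (GTF/BED/bedGraph/TSV/JSON);
`demo/manifest.json` records parameters, seeds and per-stage counts, and
rerunning with the same seed reproduces every file byte for byte.

Individual stages are also available (`parclip simulate`, `collapse`,
`align`, `callpeaks`, `motifs`, `profiles`, `stats`, `convert`) and the
whole surface can be driven from Python (`import parclip`).

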