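# Methods

This note documents the statistical procedures, the simulator's assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and strand conventions

All internal coordinates are 0-based half-open on the forward genomic
strand; GTF I/O converts to 1-based inclusive, BED stays 0-based. Reads are
strand-resolved (PAR-CLIP libraries are strand-specific): a read from a
minus-strand transcript is stored with its genomic interval and strand "−",
and its substitutions are recorded with genomic-strand bases. A cross-link
T→C on the transcript sense strand therefore appears as **T>C on "+"
features and A>G on "−" features**; every downstream consumer (contig
builder, cross-link flagging, T-C profiles) tests both forms.

## Duplicate collapsing and unique alignment

Collapsing is by exact full-sequence identity — no UMI logic — with
multiplicities retained for bookkeeping. Output order is lexicographic so
the stage is deterministic.

The aligner is an exhaustive substitution-only matcher: for each collapsed
read it computes the mismatch count at every offset of every chromosome on
both strands (vectorized over offsets) and reports the read iff exactly one
placement attains the minimum count and that count is ≤ `max_mismatches`
(default 2; the value is a free parameter surfaced in configuration). Ties
across placements mean multi-mapping and the read is excluded, which is the
unique-mapping filter applied as a matter of course to CLIP data. The
O(genome × reads) cost restricts this to small (≲ 1 Mb) genomes — it exists
so that the *analysis*, not alignment heuristics, is the tested surface;
real libraries enter through `accept_prealigned` (SAM with MD tags, or the
package's BED6+substitutions dialect). Indel-containing SAM records are
dropped and counted: the whole pipeline models substitutions only.

## Randomization FDR and contigs

For a feature of length L with n overlapping reads, the null model
redistributes the n reads (lengths preserved, clipped to the feature;
starts uniform on [0, L − length]) `n_iter` = 100 times. For every height
h in 1..max(coverage):

    FDR(h) = mean over randomizations of #positions with coverage >= h
             -----------------------------------------------------------
                     #positions with observed coverage >= h

capped at 1. Two open points and how they are resolved:

- **Positions, not regions.** Exceedance is counted over positions; the
  alternative (discrete regions) is not used, and the choice is visible in
  `FdrTable.observed`.
- **Monotone cleanup.** Raw Monte-Carlo ratios need not be monotone at
  sparse heights, so the reported FDR is the running minimum over
  increasing h (cleaned(h) = min over h′ ≤ h of raw(h′)). This makes FDR
  non-increasing in h and `h_min` — the smallest h with FDR ≤ α — well
  defined; every height above `h_min` is then also significant. α defaults
  to 0.01.
- **Direction of the ratio.** The estimator is expected-false over
  observed (small FDR = rarer than random), the only direction under which
  "FDR ≤ 0.01" selects enriched heights.

Randomization uses collapsed reads with multiplicity 1 each (unique cDNAs),
so PCR depth cannot manufacture significance. Reads overlapping two
features are used in both features' tests; contigs are deduplicated by
coordinates so no interval is emitted twice.

Contigs are maximal runs of positions with coverage ≥ `h_min`, annotated
per position with coverage, T-C substitution count (each overlapping
read's substitution counted once — all T-C events weighted equally) and
covered-T count (coverage at positions whose sense-strand reference base
is T). The accuracy of the 100-iteration estimate is checked against an
independent 10⁵-iteration Monte-Carlo oracle (agreement within 3× combined
Monte-Carlo standard error at every height), and calibration under a
uniform null over 200 features stays below a 5% flag rate at α = 0.01.

## k-mer Z-scores and cross-linked motifs

k-mers (k = 4–6) are counted with **distinct-per-contig semantics**: a
k-mer counts at most once per contig regardless of how often it recurs,
removing the bias of homopolymeric or repetitive stretches. The background
is `n_shuffles` = 100 independent shuffles of each contig sequence,
counted the same way; z = (observed − mean)/sd with the sample sd
(ddof = 1). The default shuffle is mononucleotide (composition-preserving
permutation), the simplest defensible null; a dinucleotide-preserving
shuffle (random Eulerian walk on the dinucleotide multigraph) is available
via `background="dinucleotide"` for sensitivity analysis. Shuffling is at
contig level, not read level. Degenerate cases: sd = 0 with observed >
mean ⇒ z = +∞ (ranks above all finite z); observed = mean ⇒ z = 0. Ties
are broken by observed count descending, then lexicographically.

Motif scanning is exact substring search on both strands (RNA motifs with
U→T applied; overlapping occurrences allowed). Default motif sets: Nab3
{UCUU, CUUG}, Nrd1 {UGUA, GUAG}; the extended AU-rich Nrd1 motifs {UGUAA,
UGUAAA} are available as configuration. A hit inside a contig is
**cross-linked** when ≥ 1 position of its span carries a T-C count ≥ 1;
`--flank N` widens the window because cross-link substitutions can
concentrate near rather than strictly inside a motif. Hits outside all
contigs are excluded from the identified set but retained genome-wide.

## Profiles

Metagene binning rescales each transcript segment separately — 10 bins per
UTR, 130 for the CDS — and concatenates the axes. With segment length L
and B bins, nucleotide o maps to bin ⌊oB/L⌋ when L ≥ B; when L < B the
bins are finer than nucleotides and the nucleotide's unit mass is split
evenly across the bins b with ⌊bL/B⌋ = o. Both directions conserve total
mass exactly (asserted in tests), and short UTRs cannot create spurious
spikes. Motif items contribute their full 4–6 nt span, not a single point.
Transcripts lacking a UTR contribute only to the segments they have.

Binding probability is the pooled-before-ratio form: cross-linked-motif
density summed over genes, divided per bin by all-motif density summed
over genes (per-gene ratio averaging is *not* used). Zero-denominator bins
report 0 and are masked.

Anchor profiles count item nucleotides at signed offsets −flank..+flank
(default 500) from TSSs, stop codons or poly(A) sites, with minus-strand
windows flipped so downstream is transcriptional downstream; bin flank is
the anchor itself (1,001 bins at the default). T-C percentage profiles
cover flank + motif + flank (104 bins for 4-mers at flank 50, motif start
at index 50) and report 100 × ΣT-C/ΣTs per bin, masking bins with no
covered Ts.

Per-gene bin matrices carry the same masses per transcript row (row mass =
that gene's item nucleotides) and are exported in a Cluster-3.0-compatible
layout. Row clustering delegates to scikit-learn's KMeans (Lloyd,
`n_init` restarts, seeded) — deterministic for a fixed seed. A per-gene
TSS-anchored matrix (±500 nt, each gene's own cross-linked hits around its
own TSS) is exported alongside, rows ordered by cluster label and then by
total mass descending, for external heat-map rendering.

## Feature statistics

Overlap counting is ≥ 1 nt on the matching strand (sense by default,
antisense available); an item overlapping two features counts for both.
Intron-containing transcripts — those with more than one exon record in
the GTF — are excluded before counting. Cross-linked motifs are assigned
to 5′UTR/CDS/3′UTR by the segment containing their 5′-most nucleotide in
transcript orientation (deterministic, and consistent with the 5′-bias
analyses); a majority-overlap rule was considered and rejected because it
ties at even splits. Transcript length is defined everywhere as 5′UTR +
CDS + 3′UTR. The length comparison uses scipy's two-sample
Kolmogorov–Smirnov test in asymptotic mode (sample sizes in use are
large); the reported threshold fraction defaults to 782 nt.

## The simulator: what it emulates and what it does not

The generator emulates the structure PAR-CLIP signal extraction depends
on: reads concentrated over planted protein-bound sites within
transcripts (every bound read covers its site's cross-link position), a
uniform within-transcript background, T→C conversion at cross-link
positions with probability `tc_rate`, uniform per-base sequencing error,
and exact-copy PCR duplicates. Defaults: 4,000 reads of 30 ± 5 nt over a
40 kb genome with 20 intronless genes, `bound_fraction` 0.7, `tc_rate`
0.5, `error_rate` 0.001, `duplication_rate` 0.1. Conversion efficiency in
real PAR-CLIP libraries is not well characterized, so `tc_rate` is a free
parameter with an intermediate default; planted sites are spaced ≥ 30 nt
apart so a single read never spans more than two cross-link positions.
CDS lengths are multiples of 3 and end in a real stop codon written into
the genome, so stop-codon overlap analysis is meaningful.

Deliberately not modeled: indels, quality-score structure (a constant
placeholder), introns, expression-level heterogeneity between genes,
ligation/RNase sequence biases, and cross-link sites without a T. Passing
tests therefore demonstrate correctness of the *computations* under a
clean generative model — uniform nulls really are uniform — not
robustness to every artifact of real libraries; real data should enter
through `accept_prealigned` after an external aligner.

## Determinism and problem sizes

Every random stage takes an explicit seed (numpy `default_rng`); the
pipeline derives per-stage seeds from one top-level seed, and a repeated
run reproduces every output file byte for byte (hashed in tests). The
validation experiments run at desk scale: 1 kb features with 50 stacked
reads for the FDR oracle, 200 features / 320 kb for null calibration, 20
seeded runs with 16 planted UCUU sites each (≥ 50 reads per site) for
motif recovery, and ~1,500–4,000-read scenarios elsewhere; the full suite
completes in about a minute on one CPU. The planted-site density in the
recovery experiment is chosen so the enrichment signal is carried by ~16
contigs — the desk-scale analogue of the thousands of significant
intervals a genome-wide library yields; with many fewer sites the maximum
noise Z among all 256 4-mers approaches the planted motif's Z and the
experiment stops measuring the method.

## Known limitations

- The exhaustive aligner is quadratic and not usable beyond ~1 Mb genomes.
- The randomization null preserves only read lengths, not local coverage
  autocorrelation; the FDR is conservative rather than exact, and highly
  covered features need larger heights to reach significance (an intended
  property, but it under-calls uniformly saturated genes).
- Region-level FDR (over discrete enriched regions rather than positions)
  is not implemented.
- The k-mer background shuffles contigs, so motifs overlapping contig
  boundaries are invisible to the Z-score (not to the genome-wide scan).
- GTF parsing covers the 5UTR/CDS/3UTR + exon dialect this package writes
  and reads; it is not a general-purpose GFF parser.
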