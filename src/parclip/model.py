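"""Core domain objects shared across the pipeline.

All coordinates are 0-based half-open on the forward genomic strand;
GTF import/export converts to and from 1-based inclusive. Strand is
"+" or "-". Substitutions are recorded in genomic coordinates with
genomic-strand reference and read bases, so a sense-strand T>C on a
minus-strand transcript appears here as A>G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def rna_to_dna(motif: str) -> str:
    """UCUU -> TCTT (RNA motif label to genomic sense-strand DNA)."""
    return motif.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True, order=True)
class Substitution:
    pos: int  # genomic, 0-based
    ref: str  # genomic-strand base in the reference
    alt: str  # genomic-strand base read at that position

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"substitution at {self.pos} has ref == alt ({self.ref})")


@dataclass
class AlignedRead:
    """A uniquely mapped cDNA with its mismatches against the reference."""

    chrom: str
    start: int
    end: int
    strand: str
    substitutions: tuple[Substitution, ...] = ()
    multiplicity: int = 1
    read_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        for s in self.substitutions:
            if not (self.start <= s.pos < self.end):
                raise ValueError(
                    f"substitution at {s.pos} outside read [{self.start},{self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_tc(self, sub: Substitution) -> bool:
        """True if this substitution is a cross-link signature on this read's
        strand: T>C on "+", A>G on "-" (genomic coordinates)."""
        if self.strand == "+":
            return sub.ref == "T" and sub.alt == "C"
        return sub.ref == "A" and sub.alt == "G"


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class TranscriptModel:
    """An intronless transcript with contiguous 5'UTR, CDS and 3'UTR.

    Segment coordinates are genomic; on the "-" strand the 5'UTR has the
    highest genomic coordinates. TSS is the transcript 5' end and the
    polyadenylation site its 3' end, both in transcript orientation.
    """

    transcript_id: str
    chrom: str
    strand: str
    utr5: tuple[int, int] | None
    cds: tuple[int, int]
    utr3: tuple[int, int] | None
    feature_class: str = "mRNA"

    @property
    def start(self) -> int:
        parts = [self.cds] + [s for s in (self.utr5, self.utr3) if s]
        return min(s[0] for s in parts)

    @property
    def end(self) -> int:
        parts = [self.cds] + [s for s in (self.utr5, self.utr3) if s]
        return max(s[1] for s in parts)

    @property
    def length(self) -> int:
        """Transcript length including UTRs."""
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic position of the transcript 5' end (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pa_site(self) -> int:
        """Genomic position of the transcript 3' end (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def stop_codon(self) -> tuple[int, int]:
        """Genomic interval of the last codon of the CDS."""
        if self.strand == "+":
            return (self.cds[1] - 3, self.cds[1])
        return (self.cds[0], self.cds[0] + 3)

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    def segment_of(self, genomic_pos: int) -> str | None:
        """Which segment (utr5/cds/utr3) contains a genomic position."""
        for name, seg in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)):
            if seg and seg[0] <= genomic_pos < seg[1]:
                return name
        return None

    def to_transcript_coord(self, genomic_pos: int) -> int:
        """Offset from the TSS in transcript (5'->3') orientation."""
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos


@dataclass
class CoverageTrack:
    """Per-position read coverage over one feature's interval."""

    feature_id: str
    chrom: str
    start: int  # genomic coordinate of heights[0]
    strand: str
    heights: np.ndarray

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=np.int64)
        if (self.heights < 0).any():
            raise ValueError("negative coverage")

    @property
    def end(self) -> int:
        return self.start + len(self.heights)


@dataclass
class FdrTable:
    """Randomization FDR per coverage height for one feature.

    ``heights`` runs 1..max observed coverage; ``observed[i]`` is the number
    of feature positions with coverage >= heights[i]; ``rand_mean[i]`` the
    mean such count over randomizations. ``fdr_raw`` is rand_mean/observed
    capped at 1; ``fdr`` is the monotone cleanup (running minimum over
    increasing height), non-increasing in h.
    """

    feature_id: str
    heights: np.ndarray
    observed: np.ndarray
    rand_mean: np.ndarray
    fdr_raw: np.ndarray
    fdr: np.ndarray
    alpha: float = 0.01
    rand_counts: np.ndarray | None = None  # per-iteration exceedance counts

    def h_min_at(self, alpha: float) -> int | None:
        """Smallest height whose cleaned FDR is <= alpha, or None."""
        idx = np.nonzero(self.fdr <= alpha)[0]
        if idx.size == 0:
            return None
        return int(self.heights[idx[0]])

    @property
    def h_min(self) -> int | None:
        return self.h_min_at(self.alpha)

    @property
    def empty(self) -> bool:
        return self.heights.size == 0


@dataclass
class Contig:
    """Maximal run of positions at or above a feature's minimum significant
    height, carrying per-position coverage, T-C substitution counts and
    covered-T counts (sense strand of the feature)."""

    chrom: str
    start: int
    end: int
    strand: str
    coverage: np.ndarray
    tc_count: np.ndarray
    t_coverage: np.ndarray
    feature_id: str = ""
    sequence: str = ""  # sense-strand sequence

    def __post_init__(self):
        n = self.end - self.start
        for arr in (self.coverage, self.tc_count, self.t_coverage):
            if len(arr) != n:
                raise ValueError("per-position array length != contig length")
        if (self.tc_count > self.coverage).any():
            raise ValueError("T-C count exceeds coverage")

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MotifHit:
    """A genomic occurrence of a protein's binding motif."""

    chrom: str
    start: int
    end: int
    strand: str
    motif: str  # RNA-alphabet label, e.g. UCUU
    protein: str
    crosslinked: bool = False
    host_feature: str | None = None

    def __post_init__(self):
        if self.end - self.start != len(self.motif):
            raise ValueError("hit span does not match motif length")

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


@dataclass
class BinProfile:
    """Per-bin densities (or ratios/percentages) on a fixed axis."""

    values: np.ndarray
    n_items: int = 0
    boundaries: dict = field(default_factory=dict)  # label -> first bin index
    mask: np.ndarray | None = None  # True where the bin had no support

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def same_axis(self, other: "BinProfile") -> bool:
        return self.n_bins == other.n_bins and self.boundaries == other.boundaries
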