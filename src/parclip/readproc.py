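"""Duplicate collapsing and unique genomic alignment of cDNA reads.

PCR duplicates are removed by collapsing exact full-sequence copies.
Mapping is an exhaustive substitution-only matcher over both strands of the
(small, synthetic) genome: a read is reported iff exactly one placement
attains the minimum mismatch count and that count is <= max_mismatches,
mirroring the unique-mapping filter real pipelines apply after alignment.
Mismatches are recorded in genomic coordinates with genomic-strand bases,
so a sense-strand T>C cross-link signature on a minus-strand read surfaces
as A>G. Pre-aligned data can be injected through ``accept_prealigned``
(SAM with MD tags, or the BED6+substitutions dialect this package writes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import read_reads_bed
from .model import AlignedRead, Substitution, reverse_complement


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    multiplicity: int

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class AlignStats:
    total: int = 0
    aligned: int = 0
    unmapped: int = 0
    multimapped: int = 0
    dropped_secondary: int = 0
    dropped_unparseable: int = 0
    notes: list[str] = field(default_factory=list)


def collapse_duplicates(reads) -> list[CollapsedRead]:
    """Collapse exact duplicate sequences; output sorted lexicographically.

    Accepts (read_id, sequence) pairs or bare sequences.
    """
    counts: Counter[str] = Counter()
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        counts[seq] += 1
    return [CollapsedRead(seq, counts[seq]) for seq in sorted(counts)]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_profile(genome_arr: np.ndarray, read_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of the read at every genome offset (vectorised scan)."""
    n, length = len(genome_arr), len(read_arr)
    if length > n:
        return np.empty(0, dtype=np.int32)
    n_off = n - length + 1
    mm = np.zeros(n_off, dtype=np.int32)
    for j in range(length):
        mm += genome_arr[j : j + n_off] != read_arr[j]
    return mm


def align_unique(
    collapsed: list[CollapsedRead],
    genome: dict[str, str],
    max_mismatches: int = 2,
) -> tuple[list[AlignedRead], AlignStats]:
    """Exhaustively map collapsed reads; keep only unique best placements.

    A placement is a (chrom, offset, strand) triple; "-" strand means the
    reverse complement of the read matches the forward genome there. Ties
    at the minimum mismatch count across placements mean the read is
    multi-mapping and it is excluded.
    """
    arrs = {chrom: _encode(seq) for chrom, seq in genome.items()}
    stats = AlignStats(total=len(collapsed))
    out: list[AlignedRead] = []
    for idx, cr in enumerate(collapsed):
        fwd = _encode(cr.sequence)
        rev = _encode(reverse_complement(cr.sequence))
        best = None  # (mm, chrom, offset, strand)
        n_best = 0
        for chrom, garr in arrs.items():
            for strand, rarr in (("+", fwd), ("-", rev)):
                mm = _mismatch_profile(garr, rarr)
                if mm.size == 0:
                    continue
                lo = int(mm.min())
                if lo > max_mismatches:
                    continue
                hits = int((mm == lo).sum())
                if best is None or lo < best[0]:
                    off = int(np.argmin(mm))
                    best = (lo, chrom, off, strand)
                    n_best = hits
                elif lo == best[0]:
                    n_best += hits
        if best is None:
            stats.unmapped += 1
            continue
        if n_best > 1:
            stats.multimapped += 1
            continue
        mmcount, chrom, off, strand = best
        placed = fwd if strand == "+" else rev
        garr = arrs[chrom]
        subs = []
        for j in np.nonzero(garr[off : off + len(placed)] != placed)[0]:
            j = int(j)
            subs.append(
                Substitution(off + j, chr(garr[off + j]), chr(placed[j]))
            )
        out.append(
            AlignedRead(
                chrom=chrom,
                start=off,
                end=off + len(placed),
                strand=strand,
                substitutions=tuple(subs),
                multiplicity=cr.multiplicity,
                read_id=f"aln{idx:06d}",
            )
        )
        stats.aligned += 1
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return out, stats


def accept_prealigned(path, fmt: str = "bed") -> tuple[list[AlignedRead], AlignStats]:
    """Ingest pre-aligned reads with substitution records.

    fmt="bed": the BED6+substitutions dialect written by this package.
    fmt="sam": SAM with MD tags (substitutions recovered from MD+SEQ);
    secondary/supplementary/unmapped records and records without an MD tag
    are dropped and counted.
    """
    if fmt == "bed":
        reads = read_reads_bed(path)
        stats = AlignStats(total=len(reads), aligned=len(reads))
        return reads, stats
    if fmt == "sam":
        return _read_sam(path)
    raise ValueError(f"unknown pre-aligned format: {fmt}")


def _read_sam(path) -> tuple[list[AlignedRead], AlignStats]:
    import pysam

    stats = AlignStats()
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            stats.total += 1
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.dropped_secondary += 1
                continue
            if not rec.has_tag("MD"):
                stats.dropped_unparseable += 1
                stats.notes.append(f"{rec.query_name}: no MD tag")
                continue
            subs = []
            ok = True
            for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None:
                    ok = False  # indels are outside this pipeline's model
                    break
                read_base = rec.query_sequence[qpos].upper()
                if ref_base is None:
                    ok = False
                    break
                ref_base = ref_base.upper()
                if ref_base != read_base:
                    subs.append(Substitution(rpos, ref_base, read_base))
            if not ok:
                stats.dropped_unparseable += 1
                continue
            out.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    substitutions=tuple(subs),
                    multiplicity=1,
                    read_id=rec.query_name,
                )
            )
            stats.aligned += 1
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return out, stats
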