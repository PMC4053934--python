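"""Overlap counting, per-class summaries, region assignment and length tests.

Answers the bookkeeping questions of a cross-linking analysis: which
annotation classes carry motifs and cross-linked motifs (and what fraction
of genes in each class), where within transcripts the cross-linked motifs
fall (5'UTR / CDS / 3'UTR, assigned by the hit's 5'-most nucleotide), how
often Nrd1-style motifs coincide with stop codons, and whether targeted
transcripts differ in length from the transcriptome at large
(two-sample Kolmogorov-Smirnov).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Interval, MotifHit, TranscriptModel


def _as_interval(item) -> Interval:
    return item if isinstance(item, Interval) else item.interval()


def intron_containing_ids(gtf_path) -> set[str]:
    """Transcript ids with more than one exon record in a GTF file."""
    from .io import _parse_gtf_attrs

    exon_counts: Counter[str] = Counter()
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9 and fields[2] == "exon":
                exon_counts[_parse_gtf_attrs(fields[8])["transcript_id"]] += 1
    return {tid for tid, n in exon_counts.items() if n > 1}


def filter_intronless(transcripts: list[TranscriptModel], gtf_path=None) -> list[TranscriptModel]:
    """Drop intron-containing transcripts (those with >1 exon record)."""
    if gtf_path is None:
        return list(transcripts)
    excluded = intron_containing_ids(gtf_path)
    return [t for t in transcripts if t.transcript_id not in excluded]


def count_overlaps(items, features, strand_policy: str = "sense") -> dict[str, int]:
    """Per-feature count of items with >= 1 nt overlap.

    strand_policy "sense" requires matching strands, "antisense" opposite
    strands, "both" ignores strand. An item overlapping several features
    counts for each of them.
    """
    flip = {"+": "-", "-": "+"}
    counts = {getattr(f, "transcript_id", None) or f.feature_id: 0 for f in features}
    intervals = [_as_interval(it) for it in items]
    for f in features:
        fid = getattr(f, "transcript_id", None) or f.feature_id
        fiv = f.interval() if hasattr(f, "interval") else f
        want = fiv.strand if strand_policy == "sense" else flip[fiv.strand]
        for iv in intervals:
            if iv.chrom != fiv.chrom:
                continue
            if strand_policy != "both" and iv.strand != want:
                continue
            if iv.start < fiv.end and fiv.start < iv.end:
                counts[fid] += 1
    return counts


@dataclass
class ClassSummary:
    feature_class: str
    genes_total: int
    genes_with_motif: int
    genes_with_crosslinked_motif: int
    pct_genes_with_motif: float
    pct_genes_with_crosslinked_motif: float
    pct_hits_crosslinked: float  # share of genomic hits in this class that cross-linked
    empty: bool = False


def class_percentages(
    all_hits: list[MotifHit],
    identified_hits: list[MotifHit],
    transcripts: list[TranscriptModel],
) -> list[ClassSummary]:
    """Per annotation class: how many genes carry a motif, how many carry a
    cross-linked motif, and what share of the class's genomic motif
    occurrences are cross-linked."""
    crosslinked = [h for h in identified_hits if h.crosslinked]
    by_class: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_class.setdefault(t.feature_class, []).append(t)
    out = []
    for cls in sorted(by_class):
        members = by_class[cls]
        n = len(members)
        with_motif = count_overlaps(all_hits, members)
        with_xl = count_overlaps(crosslinked, members)
        genes_with_motif = sum(1 for v in with_motif.values() if v > 0)
        genes_with_xl = sum(1 for v in with_xl.values() if v > 0)
        hits_in_class = sum(with_motif.values())
        xl_in_class = sum(with_xl.values())
        if n == 0:
            out.append(ClassSummary(cls, 0, 0, 0, 0.0, 0.0, 0.0, empty=True))
            continue
        out.append(
            ClassSummary(
                feature_class=cls,
                genes_total=n,
                genes_with_motif=genes_with_motif,
                genes_with_crosslinked_motif=genes_with_xl,
                pct_genes_with_motif=100.0 * genes_with_motif / n,
                pct_genes_with_crosslinked_motif=100.0 * genes_with_xl / n,
                pct_hits_crosslinked=(100.0 * xl_in_class / hits_in_class) if hits_in_class else 0.0,
            )
        )
    return out


@dataclass
class RegionDistribution:
    utr5: int = 0
    cds: int = 0
    utr3: int = 0
    no_utr_fallback: int = 0  # hits forced into cds because the host lacks UTRs
    unassigned: int = 0  # hits outside every transcript

    @property
    def total_assigned(self) -> int:
        return self.utr5 + self.cds + self.utr3


def region_assignment(
    hits: list[MotifHit],
    transcripts: list[TranscriptModel],
    mode: str = "start",
) -> RegionDistribution:
    """Assign each hit to a transcript segment.

    mode="start" (default): the segment containing the hit's 5'-most
    nucleotide in transcript orientation. mode="majority": the segment
    with the largest nucleotide overlap, ties broken 5' to 3'.
    """
    if mode not in ("start", "majority"):
        raise ValueError(f"unknown assignment mode: {mode}")
    dist = RegionDistribution()
    for hit in hits:
        lead = hit.start if hit.strand == "+" else hit.end - 1
        host = next(
            (
                t
                for t in transcripts
                if t.chrom == hit.chrom and t.strand == hit.strand and t.start <= lead < t.end
            ),
            None,
        )
        if host is None:
            dist.unassigned += 1
            continue
        if mode == "start":
            seg = host.segment_of(lead)
        else:
            # iterate in transcript 5'->3' order so ties go to the 5' segment
            best, best_ov = None, 0
            for name in ("utr5", "cds", "utr3"):
                segment = getattr(host, name)
                if segment is None:
                    continue
                ov = min(hit.end, segment[1]) - max(hit.start, segment[0])
                if ov > best_ov:
                    best, best_ov = name, ov
            seg = best
        if seg == "utr5":
            dist.utr5 += 1
        elif seg == "utr3":
            dist.utr3 += 1
        elif seg == "cds":
            dist.cds += 1
        else:  # host without annotated UTRs at that position
            dist.cds += 1
            dist.no_utr_fallback += 1
    return dist


def stop_codon_overlap(hits: list[MotifHit], transcripts: list[TranscriptModel]) -> float:
    """Fraction of the given hits sharing >= 1 nt with a stop codon on the
    same strand. Zero hits give 0."""
    if not hits:
        return 0.0
    stops = [
        Interval(t.chrom, t.stop_codon[0], t.stop_codon[1], t.strand) for t in transcripts
    ]
    n_overlap = 0
    for hit in hits:
        if any(
            s.chrom == hit.chrom and s.strand == hit.strand and hit.start < s.end and s.start < hit.end
            for s in stops
        ):
            n_overlap += 1
    return n_overlap / len(hits)


@dataclass
class LengthComparison:
    d_statistic: float
    p_value: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    fraction_above: float
    threshold: int


def length_comparison(
    target_lengths,
    all_lengths,
    threshold: int = 782,
    n_hist_bins: int = 20,
) -> LengthComparison:
    """Two-sample KS comparison of target transcript lengths against all
    transcripts, plus a length histogram and the fraction of targets
    longer than the threshold (default 782 nt)."""
    target = np.asarray(list(target_lengths), dtype=float)
    background = np.asarray(list(all_lengths), dtype=float)
    if target.size == 0 or background.size == 0:
        raise ValueError("both length samples must be non-empty")
    res = sps.ks_2samp(target, background, method="asymp")
    counts, edges = np.histogram(target, bins=n_hist_bins)
    return LengthComparison(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        hist_counts=counts,
        hist_edges=edges,
        fraction_above=float((target > threshold).mean()),
        threshold=threshold,
    )


def target_table(
    transcripts: list[TranscriptModel],
    identified_hits: list[MotifHit],
) -> pd.DataFrame:
    """Per-transcript table of motif and cross-linked-motif content
    (transcript_id, class, n_motifs, n_crosslinked, regions hit)."""
    rows = []
    for t in transcripts:
        mine = [
            h
            for h in identified_hits
            if h.chrom == t.chrom and h.strand == t.strand and h.start < t.end and t.start < h.end
        ]
        xl = [h for h in mine if h.crosslinked]
        regions = sorted(
            {
                t.segment_of(h.start if h.strand == "+" else h.end - 1) or "cds"
                for h in xl
            }
        )
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "feature_class": t.feature_class,
                "length": t.length,
                "n_motifs": len(mine),
                "n_crosslinked": len(xl),
                "regions": ",".join(regions) if regions else ".",
            }
        )
    return pd.DataFrame(rows)
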