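"""Randomization-FDR peak calling and T-C-aware contig construction.

With no negative-control library, significance of a coverage height h
within a feature is assessed by redistributing the feature's reads at
uniform random starts (lengths preserved, clipped to the feature) n_iter
times and comparing exceedance counts:

    FDR(h) = E[# positions with randomized coverage >= h] /
             (# positions with observed coverage >= h), capped at 1.

The smallest h whose (monotone-cleaned) FDR is <= alpha is the feature's
minimum significant height h_min; maximal runs of positions at coverage
>= h_min are the selected intervals, and contigs annotate those runs with
per-position coverage, T-C substitution counts (T>C on "+", A>G on "-")
and covered-T counts. Collapsed reads enter with multiplicity 1 each
(unique cDNAs), so PCR duplication depth never inflates significance.
"""

from __future__ import annotations

import numpy as np

from .model import Contig, CoverageTrack, FdrTable, Interval, reverse_complement


def _feature_interval(feature) -> Interval:
    if isinstance(feature, Interval):
        return feature
    return feature.interval()


def _overlapping(reads, iv: Interval):
    return [
        r
        for r in reads
        if r.chrom == iv.chrom and r.strand == iv.strand and r.start < iv.end and r.end > iv.start
    ]


def coverage_track(reads, feature) -> CoverageTrack:
    """Per-position coverage of strand-matched reads over the feature.

    Each aligned (collapsed) read contributes 1 at every position it
    covers, clipped to the feature interval.
    """
    iv = _feature_interval(feature)
    n = iv.length
    diff = np.zeros(n + 1, dtype=np.int64)
    for r in _overlapping(reads, iv):
        a = max(r.start, iv.start) - iv.start
        b = min(r.end, iv.end) - iv.start
        diff[a] += 1
        diff[b] -= 1
    heights = np.cumsum(diff[:-1])
    fid = getattr(feature, "transcript_id", None) or getattr(feature, "feature_id", "") or ""
    return CoverageTrack(feature_id=fid, chrom=iv.chrom, start=iv.start, strand=iv.strand, heights=heights)


def _exceedance(heights: np.ndarray, max_h: int) -> np.ndarray:
    """counts[h-1] = number of positions with coverage >= h, h = 1..max_h."""
    if max_h == 0:
        return np.zeros(0, dtype=np.int64)
    capped = np.minimum(heights, max_h)
    binc = np.bincount(capped, minlength=max_h + 1)
    # positions with coverage >= h = total - positions with coverage < h
    less_than = np.cumsum(binc)[:-1]  # < 1, < 2, ..., < max_h
    return heights.size - less_than


def height_fdr(
    reads,
    feature,
    n_iter: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
    keep_rand_counts: bool = False,
) -> FdrTable:
    """Randomization FDR table for every height observed in the feature.

    Randomized placements draw each read's start uniformly from
    [0, feature_length - read_length]; reads longer than the feature are
    placed at the feature start and clipped.
    """
    iv = _feature_interval(feature)
    track = coverage_track(reads, feature)
    max_h = int(track.heights.max(initial=0))
    fid = track.feature_id
    if max_h == 0:
        z = np.zeros(0)
        return FdrTable(fid, np.zeros(0, dtype=int), z.astype(int), z, z, z, alpha)

    observed = _exceedance(track.heights, max_h)
    lengths = np.array(
        [min(r.end, iv.end) - max(r.start, iv.start) for r in _overlapping(reads, iv)],
        dtype=np.int64,
    )
    # randomized reads keep their within-feature overlap length; a read
    # longer than the feature covers it fully wherever it is placed
    lengths = np.minimum(lengths, iv.length)
    n_reads = lengths.size
    L = iv.length

    rng = np.random.default_rng(seed)
    counts = np.zeros((n_iter, max_h), dtype=np.int64)
    chunk = max(1, min(n_iter, 2_000_000 // max(L, 1)))
    diff = np.zeros((chunk, L + 1), dtype=np.int32)
    row_idx = np.repeat(np.arange(chunk), n_reads)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        starts = rng.integers(0, L - lengths + 1, size=(m, n_reads))
        ends = starts + lengths
        diff[:m] = 0
        ridx = row_idx[: m * n_reads]
        np.add.at(diff[:m], (ridx, starts.ravel()), 1)
        np.add.at(diff[:m], (ridx, ends.ravel()), -1)
        cov = np.cumsum(diff[:m, :-1], axis=1)
        capped = np.minimum(cov, max_h)
        for i in range(m):
            binc = np.bincount(capped[i], minlength=max_h + 1)
            counts[done + i] = L - np.cumsum(binc)[:-1]
        done += m

    rand_mean = counts.mean(axis=0)
    fdr_raw = np.minimum(rand_mean / observed, 1.0)
    fdr = np.minimum.accumulate(fdr_raw)
    table = FdrTable(
        fid,
        np.arange(1, max_h + 1),
        observed,
        rand_mean,
        fdr_raw,
        fdr,
        alpha,
    )
    if keep_rand_counts:
        table.rand_counts = counts
    return table


def significant_intervals(track: CoverageTrack, h_min: int) -> list[Interval]:
    """Maximal runs of positions with coverage >= h_min, in genomic order."""
    mask = track.heights >= h_min
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [
        Interval(track.chrom, track.start + int(a), track.start + int(b), track.strand)
        for a, b in zip(starts, ends)
    ]


def build_contigs(intervals, reads, genome: dict[str, str], feature_id: str = "") -> list[Contig]:
    """Annotate each selected interval with per-position coverage, T-C
    substitution counts and covered-T counts.

    A T-C event is a T>C substitution on a "+" interval or A>G on a "-"
    interval (genomic coordinates); each overlapping read's substitution
    counts once. The covered-T count at a position is its coverage if the
    sense-strand reference base there is T, else 0.
    """
    out = []
    for iv in intervals:
        n = iv.length
        cov_diff = np.zeros(n + 1, dtype=np.int64)
        tc = np.zeros(n, dtype=np.int64)
        for r in reads:
            if r.chrom != iv.chrom or r.strand != iv.strand:
                continue
            if r.start >= iv.end or r.end <= iv.start:
                continue
            a = max(r.start, iv.start) - iv.start
            b = min(r.end, iv.end) - iv.start
            cov_diff[a] += 1
            cov_diff[b] -= 1
            for s in r.substitutions:
                if iv.start <= s.pos < iv.end and r.is_tc(s):
                    tc[s.pos - iv.start] += 1
        coverage = np.cumsum(cov_diff[:-1])
        chrom_seq = genome[iv.chrom]
        ref = chrom_seq[iv.start : iv.end]
        sense_t = "T" if iv.strand == "+" else "A"
        is_t = np.frombuffer(ref.encode(), dtype=np.uint8) == ord(sense_t)
        t_cov = np.where(is_t, coverage, 0)
        sequence = ref if iv.strand == "+" else reverse_complement(ref)
        out.append(
            Contig(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                strand=iv.strand,
                coverage=coverage,
                tc_count=tc,
                t_coverage=t_cov,
                feature_id=feature_id,
                sequence=sequence,
            )
        )
    return out


def call_peaks(
    reads,
    features,
    genome: dict[str, str],
    alpha: float = 0.01,
    n_iter: int = 100,
    seed: int = 0,
) -> tuple[dict[str, FdrTable], list[Interval], list[Contig]]:
    """Per-feature FDR tables, selected intervals, and deduplicated contigs.

    Reads overlapping two features are tested for both; contigs landing on
    identical coordinates are emitted once.
    """
    tables: dict[str, FdrTable] = {}
    all_contigs: list[Contig] = []
    seen: set[tuple] = set()
    intervals_all: list[Interval] = []
    for k, feature in enumerate(features):
        fid = getattr(feature, "transcript_id", None) or getattr(feature, "feature_id", f"f{k}")
        table = height_fdr(reads, feature, n_iter=n_iter, seed=seed + k, alpha=alpha)
        tables[fid] = table
        if table.empty:
            continue
        h_min = table.h_min_at(alpha)
        if h_min is None:
            continue
        track = coverage_track(reads, feature)
        ivs = significant_intervals(track, h_min)
        for contig in build_contigs(ivs, reads, genome, feature_id=fid):
            key = (contig.chrom, contig.start, contig.end, contig.strand)
            if key in seen:
                continue
            seen.add(key)
            all_contigs.append(contig)
            intervals_all.append(contig.interval())
    return tables, intervals_all, all_contigs
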