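"""Length-normalized and anchor-window profiles over transcript architecture.

Metagene profiles rescale each transcript segment to a fixed number of
bins (defaults: 10 for each UTR, 130 for the CDS/exon) and accumulate
item-nucleotide densities; anchor profiles count item nucleotides at
signed offsets from a set of anchors (TSSs, stop codons, polyadenylation
sites, motif starts), flipped on the minus strand so downstream always
means transcriptional downstream. T-C percentage profiles divide T-C
substitution counts by covered-T counts per bin around motif occurrences.

Binning rule: with segment length L and B bins, a nucleotide at offset o
(transcript orientation) maps to bin floor(o*B/L) when L >= B; when
L < B the bins are finer than nucleotides and the nucleotide's unit mass
is split evenly over the bins b with floor(b*L/B) == o. Both directions
conserve total mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BinProfile, Contig, Interval, TranscriptModel


@dataclass(frozen=True)
class ProfileConfig:
    utr5_bins: int = 10
    exon_bins: int = 130
    utr3_bins: int = 10
    tss_flank: int = 500
    motif_flank: int = 50

    def __post_init__(self):
        for name in ("utr5_bins", "exon_bins", "utr3_bins", "tss_flank", "motif_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_bins(self) -> int:
        return self.utr5_bins + self.exon_bins + self.utr3_bins

    def boundaries(self) -> dict:
        return {
            "utr5": 0,
            "cds": self.utr5_bins,
            "utr3": self.utr5_bins + self.exon_bins,
        }


def _as_interval(item) -> Interval:
    return item if isinstance(item, Interval) else item.interval()


def _segment_bins(L: int, B: int, o: int) -> tuple[np.ndarray, float]:
    """Bins (within-segment indices) and per-bin mass for nucleotide o."""
    if L >= B:
        return np.array([o * B // L]), 1.0
    bins = np.nonzero(np.arange(B) * L // B == o)[0]
    return bins, 1.0 / len(bins)


def _transcript_bin_masses(
    t: TranscriptModel, positions: np.ndarray, config: ProfileConfig
) -> np.ndarray:
    """Distribute unit mass per genomic position onto the 10+130+10 axis."""
    values = np.zeros(config.n_bins)
    segs = (
        ("utr5", t.utr5, 0, config.utr5_bins),
        ("cds", t.cds, config.utr5_bins, config.exon_bins),
        ("utr3", t.utr3, config.utr5_bins + config.exon_bins, config.utr3_bins),
    )
    for _name, seg, bin_off, B in segs:
        if seg is None:
            continue
        a, b = seg
        L = b - a
        in_seg = positions[(positions >= a) & (positions < b)]
        for pos in in_seg:
            o = pos - a if t.strand == "+" else b - 1 - pos
            bins, mass = _segment_bins(L, B, int(o))
            values[bin_off + bins] += mass
    return values


def bin_density(
    items,
    transcripts: list[TranscriptModel],
    config: ProfileConfig | None = None,
    per_gene: bool = False,
) -> BinProfile | tuple[BinProfile, pd.DataFrame]:
    """Nucleotide densities of items over the UTR5/CDS/UTR3 bin axis.

    Each item nucleotide inside a strand-matched transcript contributes
    unit mass to the bin(s) its position rescales to; transcripts lacking
    a UTR contribute only to the segments they have. With per_gene=True a
    (transcripts x bins) matrix of the same masses is returned as well.
    """
    config = config or ProfileConfig()
    intervals = [_as_interval(it) for it in items]
    total = np.zeros(config.n_bins)
    rows = {}
    n_items_used = 0
    for t in transcripts:
        positions = []
        used = False
        for iv in intervals:
            if iv.chrom != t.chrom or iv.strand != t.strand:
                continue
            a, b = max(iv.start, t.start), min(iv.end, t.end)
            if a < b:
                positions.extend(range(a, b))
                used = True
        if used:
            n_items_used += 1
        row = _transcript_bin_masses(t, np.array(positions, dtype=np.int64), config)
        total += row
        rows[t.transcript_id] = row
    profile = BinProfile(total, n_items=len(intervals), boundaries=config.boundaries())
    if per_gene:
        matrix = pd.DataFrame.from_dict(rows, orient="index")
        matrix.index.name = "transcript_id"
        return profile, matrix
    return profile


def binding_probability(crosslinked: BinProfile, all_motifs: BinProfile) -> BinProfile:
    """Per-bin ratio of cross-linked-motif density to all-motif density.

    Bins with zero all-motif density yield 0 and are flagged in the mask.
    """
    if not crosslinked.same_axis(all_motifs):
        raise ValueError("profiles are on different bin axes")
    denom = all_motifs.values
    mask = denom == 0
    ratio = np.where(mask, 0.0, crosslinked.values / np.where(mask, 1.0, denom))
    return BinProfile(ratio, n_items=crosslinked.n_items, boundaries=dict(crosslinked.boundaries), mask=mask)


def anchor_profile(items, anchors, flank: int) -> BinProfile:
    """Item-nucleotide counts at signed offsets -flank..+flank from anchors.

    anchors: (chrom, position, strand) triples. Offsets are in transcript
    orientation (minus-strand windows are flipped); bin index = flank +
    offset, so the anchor itself is the center bin.
    """
    n_bins = 2 * flank + 1
    values = np.zeros(n_bins)
    intervals = [_as_interval(it) for it in items]
    pos_by_key: dict[tuple[str, str], np.ndarray] = {}
    for key in {(iv.chrom, iv.strand) for iv in intervals}:
        pts = np.concatenate(
            [np.arange(iv.start, iv.end) for iv in intervals if (iv.chrom, iv.strand) == key]
        )
        pos_by_key[key] = np.sort(pts)
    for chrom, pos, strand in anchors:
        pts = pos_by_key.get((chrom, strand))
        if pts is None:
            continue
        lo, hi = np.searchsorted(pts, (pos - flank, pos + flank + 1))
        window = pts[lo:hi]
        offsets = window - pos if strand == "+" else pos - window
        np.add.at(values, offsets + flank, 1.0)
    return BinProfile(values, n_items=len(intervals), boundaries={"anchor": flank})


def anchor_matrix(items, transcripts, flank: int, which: str = "tss") -> pd.DataFrame:
    """Per-transcript anchor-window profiles as a (transcripts x 2*flank+1)
    matrix: row i is the profile of transcript i's own items around its own
    anchor (the heat-map companion of anchor_profile)."""
    rows = {}
    intervals = [_as_interval(it) for it in items]
    for t in transcripts:
        (anchor,) = transcript_anchors([t], which)
        mine = [
            iv for iv in intervals
            if iv.chrom == t.chrom and iv.strand == t.strand
            and iv.start < t.end and t.start < iv.end
        ]
        if mine:
            rows[t.transcript_id] = anchor_profile(mine, [anchor], flank).values
        else:
            rows[t.transcript_id] = np.zeros(2 * flank + 1)
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.index.name = "transcript_id"
    return matrix


def transcript_anchors(transcripts, which: str = "tss") -> list[tuple[str, int, str]]:
    """Anchor triples for TSSs, stop codons (their first base in transcript
    orientation) or polyadenylation sites."""
    out = []
    for t in transcripts:
        if which == "tss":
            pos = t.tss
        elif which == "pa_site":
            pos = t.pa_site
        elif which == "stop_codon":
            sc = t.stop_codon
            pos = sc[0] if t.strand == "+" else sc[1] - 1
        else:
            raise ValueError(f"unknown anchor type: {which}")
        out.append((t.chrom, pos, t.strand))
    return out


def tc_percentage_profile(
    contigs: list[Contig],
    motif_hits,
    flank: int = 50,
    motif_len: int | None = None,
) -> BinProfile:
    """T-C substitution percentages around motif occurrences.

    The axis covers flank nt upstream, the motif span, and flank nt
    downstream in transcript orientation (104 bins for 4-nt motifs at the
    default flank of 50; the motif starts at bin index ``flank``). Each
    bin's percentage is 100 * (summed T-C counts) / (summed covered Ts)
    over all windows; bins that cover no Ts report 0 and are masked.
    """
    hits = list(motif_hits)
    if motif_len is None:
        if not hits:
            raise ValueError("cannot infer motif length from an empty hit list")
        motif_len = hits[0].end - hits[0].start
    n_bins = 2 * flank + motif_len
    tc_sum = np.zeros(n_bins)
    t_sum = np.zeros(n_bins)
    by_key: dict[tuple[str, str], list[Contig]] = {}
    for c in contigs:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    for hit in hits:
        for c in by_key.get((hit.chrom, hit.strand), ()):
            if hit.start >= c.end or hit.end <= c.start:
                continue
            for b in range(n_bins):
                off = b - flank  # offset from motif start, transcript orientation
                gpos = hit.start + off if hit.strand == "+" else hit.end - 1 - off
                if c.start <= gpos < c.end:
                    i = gpos - c.start
                    tc_sum[b] += c.tc_count[i]
                    t_sum[b] += c.t_coverage[i]
    mask = t_sum == 0
    pct = np.where(mask, 0.0, 100.0 * tc_sum / np.where(mask, 1.0, t_sum))
    return BinProfile(pct, n_items=len(hits), boundaries={"motif_start": flank, "motif_end": flank + motif_len}, mask=mask)


def kmeans_rows(matrix, k: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Cluster matrix rows with seeded k-means (best of n_restarts by
    within-cluster sum of squares); deterministic for a fixed seed."""
    from sklearn.cluster import KMeans

    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} rows available")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    return km.fit_predict(X)


def write_profile_tsv(profile: BinProfile, path, value_name: str = "density") -> None:
    with open(path, "w") as fh:
        fh.write(f"bin\t{value_name}\tmasked\n")
        for i, v in enumerate(profile.values):
            masked = int(bool(profile.mask[i])) if profile.mask is not None else 0
            fh.write(f"{i}\t{v:.10g}\t{masked}\n")


def write_matrix_cluster3(matrix: pd.DataFrame, path) -> None:
    """Tab-delimited matrix in the layout Cluster 3.0 ingests
    (UID/NAME/GWEIGHT columns then one column per bin)."""
    with open(path, "w") as fh:
        bins = "\t".join(f"bin{int(c)}" for c in matrix.columns)
        fh.write(f"UID\tNAME\tGWEIGHT\t{bins}\n")
        for uid, row in matrix.iterrows():
            vals = "\t".join(f"{v:.10g}" for v in row.to_numpy())
            fh.write(f"{uid}\t{uid}\t1\t{vals}\n")
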