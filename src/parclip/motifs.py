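"""k-mer enrichment Z-scores in contigs and cross-linked motif extraction.

Over-representation of a k-mer (4-6 nt) in read contigs is scored against
shuffled contig sequences: z = (observed - mean_shuffled) / sd_shuffled.
Counting uses distinct-per-contig semantics — a k-mer counts at most once
per contig, however many times it recurs there — which removes the bias
homopolymeric or repetitive stretches would otherwise introduce.

A motif occurrence inside a significant contig is "cross-linked" when at
least one position of its span (optionally widened by a flank) carries a
T-C substitution in an overlapping read; those occurrences are the
high-confidence binding sites the rest of the analysis consumes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import Contig, MotifHit, dna_to_rna, reverse_complement, rna_to_dna
from .synthetic import DEFAULT_MOTIFS


@dataclass(frozen=True)
class KmerStat:
    kmer: str  # RNA-alphabet label
    observed: int
    random_mean: float
    random_sd: float
    z: float


def _contig_kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def count_kmers(contigs, k: int) -> dict[str, int]:
    """Distinct-per-contig k-mer counts, summed over contigs (RNA labels).

    Contigs shorter than k contribute nothing.
    """
    counts: Counter[str] = Counter()
    for c in contigs:
        seq = c.sequence if isinstance(c, Contig) else c
        for kmer in _contig_kmers(seq, k):
            counts[kmer] += 1
    return {dna_to_rna(km): n for km, n in counts.items()}


def _mono_shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode()


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    dinucleotide multigraph; falls back to the input when a walk stalls)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    # random Eulerian-walk heuristic: reshuffle successor lists until a
    # complete walk is found (a handful of tries suffices for short contigs)
    for _ in range(10):
        trial = {a: list(bs) for a, bs in edges.items()}
        for succ in trial.values():
            rng.shuffle(succ)
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            succ = trial.get(node)
            if not succ:
                ok = False
                break
            node = succ.pop()
            out.append(node)
        if ok:
            return "".join(out)
    return seq


def kmer_zscores(
    contigs,
    k: int,
    n_shuffles: int = 100,
    seed: int = 0,
    background: str = "mononucleotide",
) -> list[KmerStat]:
    """Z-scores for every k-mer observed in the contigs, ranked.

    The background is n_shuffles composition-preserving shuffles of each
    contig sequence (mononucleotide by default, dinucleotide-preserving on
    request), counted with the same distinct-per-contig rule. Ranking is by
    z descending (an infinite z, from sd = 0 with excess observed count,
    sorts first), then observed descending, then lexicographic.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if background == "mononucleotide":
        shuffle = _mono_shuffle
    elif background == "dinucleotide":
        shuffle = _dinucleotide_shuffle
    else:
        raise ValueError(f"unknown background model: {background}")
    rng = np.random.default_rng(seed)
    sequences = [c.sequence if isinstance(c, Contig) else c for c in contigs]
    observed = count_kmers(sequences, k)  # RNA labels
    dna_kmers = {rna_to_dna(km) for km in observed}
    totals = np.zeros((n_shuffles, len(dna_kmers)), dtype=np.int64)
    index = {km: i for i, km in enumerate(sorted(dna_kmers))}
    for s in range(n_shuffles):
        for seq in sequences:
            for km in _contig_kmers(shuffle(seq, rng), k):
                j = index.get(km)
                if j is not None:
                    totals[s, j] += 1
    mean = totals.mean(axis=0)
    sd = totals.std(axis=0, ddof=1)
    stats = []
    for km_dna, j in index.items():
        km = dna_to_rna(km_dna)
        obs = observed[km]
        if sd[j] > 0:
            z = (obs - mean[j]) / sd[j]
        elif obs > mean[j]:
            z = math.inf
        elif obs < mean[j]:
            z = -math.inf
        else:
            z = 0.0
        stats.append(KmerStat(km, obs, float(mean[j]), float(sd[j]), float(z)))
    stats.sort(key=lambda st: (-st.z, -st.observed, st.kmer))
    return stats


def scan_motifs(
    genome: dict[str, str],
    motifs_by_protein: dict[str, tuple[str, ...]] | None = None,
    strands: str = "both",
) -> list[MotifHit]:
    """Every exact occurrence of each motif, overlapping allowed.

    A "-" strand hit means the motif reads off the reverse complement;
    coordinates are always forward-strand. Motifs are RNA strings (U->T
    applied before matching).
    """
    motifs_by_protein = motifs_by_protein or DEFAULT_MOTIFS
    want = ["+", "-"] if strands == "both" else [strands]
    hits: list[MotifHit] = []
    for chrom, seq in genome.items():
        for protein in sorted(motifs_by_protein):
            for motif in motifs_by_protein[protein]:
                dna = rna_to_dna(motif)
                for strand in want:
                    pattern = dna if strand == "+" else reverse_complement(dna)
                    start = seq.find(pattern)
                    while start != -1:
                        hits.append(
                            MotifHit(
                                chrom=chrom,
                                start=start,
                                end=start + len(pattern),
                                strand=strand,
                                motif=motif,
                                protein=protein,
                            )
                        )
                        start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.protein, h.motif))
    return hits


def cross_linked_motifs(hits: list[MotifHit], contigs: list[Contig], flank: int = 0) -> list[MotifHit]:
    """Motif hits inside significant contigs, flagged cross-linked when a
    T-C substitution falls within the hit span (+- flank).

    Hits outside every contig are dropped (the genome-wide set is the
    caller's input). Returns new MotifHit objects with host_feature set to
    the contig's feature.
    """
    by_key: dict[tuple[str, str], list[Contig]] = {}
    for c in contigs:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    identified: list[MotifHit] = []
    for hit in hits:
        for c in by_key.get((hit.chrom, hit.strand), ()):
            if hit.start >= c.start and hit.end <= c.end:
                a = max(c.start, hit.start - flank) - c.start
                b = min(c.end, hit.end + flank) - c.start
                crosslinked = bool(c.tc_count[a:b].any())
                identified.append(
                    MotifHit(
                        chrom=hit.chrom,
                        start=hit.start,
                        end=hit.end,
                        strand=hit.strand,
                        motif=hit.motif,
                        protein=hit.protein,
                        crosslinked=crosslinked,
                        host_feature=c.feature_id or None,
                    )
                )
                break
    return identified
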