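"""Synthetic PAR-CLIP data with known ground truth.

Builds a random genome, an intronless annotation (5'UTR/CDS/3'UTR on both
strands), plants protein-binding motifs with designated cross-link Ts, and
simulates strand-specific reads: bound reads pile up over planted sites and
carry T>C conversions at cross-link positions, background reads fall
uniformly within transcripts, and PCR duplicates are exact copies. Every
read is logged in a truth table (genomic interval, origin, introduced
substitutions in genomic coordinates) so each downstream stage can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import TranscriptModel, Substitution, reverse_complement, rna_to_dna

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Default motif sets (RNA alphabet): Nab3 binds UCUU/CUUG, Nrd1 UGUA/GUAG.
DEFAULT_MOTIFS: dict[str, tuple[str, ...]] = {
    "Nab3": ("UCUU", "CUUG"),
    "Nrd1": ("UGUA", "GUAG"),
}

#: AU-rich extended Nrd1 motifs, available behind configuration.
AU_RICH_NRD1 = ("UGUAA", "UGUAAA")


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    gc_fraction: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    chrom: str
    strand: str
    genomic_start: int
    motif: str  # RNA-alphabet label, e.g. UCUU
    crosslink_position: int  # genomic 0-based position of the converting T
    protein: str
    region: str = "cds"  # utr5 | cds | utr3

    @property
    def genomic_end(self) -> int:
        return self.genomic_start + len(self.motif)

    @property
    def site_id(self) -> str:
        return f"{self.transcript_id}:{self.genomic_start}:{self.motif}"


@dataclass(frozen=True)
class SimulationConfig:
    """Read-simulation parameters.

    tc_rate is the per-site conversion probability for a read covering a
    cross-link position; PAR-CLIP conversion efficiency is not well
    characterised, so the default is an intermediate 0.5.
    """

    n_reads: int = 4000
    read_length_mean: int = 30
    read_length_spread: int = 5
    bound_fraction: float = 0.7
    tc_rate: float = 0.5
    error_rate: float = 0.001
    duplication_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for name in ("bound_fraction", "tc_rate", "error_rate", "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRead:
    """Ground-truth record for one emitted read."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    origin: str  # site_id for bound reads, "background" otherwise
    substitutions: tuple[Substitution, ...] = ()


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(spec: GenomeSpec) -> dict[str, str]:
    """One random chromosome ("chrI") with the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc_fraction) / 2.0
    gc = spec.gc_fraction / 2.0
    draw = rng.choice(_BASES, size=spec.length, p=[at, gc, gc, at])
    return {"chrI": draw.tobytes().decode("ascii")}


def generate_annotation(
    genome: dict[str, str],
    n_genes: int,
    seed: int = 0,
    utr5_range: tuple[int, int] = (50, 150),
    cds_range: tuple[int, int] = (300, 900),
    utr3_range: tuple[int, int] = (50, 150),
    min_gap: int = 20,
    max_tries: int = 500,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Place n_genes non-overlapping transcripts on both strands.

    CDS lengths are rounded to multiples of 3 and a stop codon is written
    into the genome at the CDS 3' end (sense strand). Returns the modified
    genome and the transcript models, sorted by coordinate.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome))
    seq = bytearray(genome[chrom], "ascii")
    glen = len(seq)

    placed: list[tuple[int, int]] = []
    transcripts: list[TranscriptModel] = []
    for i in range(n_genes):
        for _attempt in range(max_tries):
            u5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
            cds_len = int(rng.integers(cds_range[0], cds_range[1] + 1))
            cds_len -= cds_len % 3
            u3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
            total = u5 + cds_len + u3
            if total + 2 * min_gap >= glen:
                continue
            start = int(rng.integers(min_gap, glen - total - min_gap))
            end = start + total
            if any(start - min_gap < pe and ps < end + min_gap for ps, pe in placed):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                utr5 = (start, start + u5)
                cds = (start + u5, start + u5 + cds_len)
                utr3 = (cds[1], end)
                stop = STOP_CODONS[int(rng.integers(3))]
                seq[cds[1] - 3 : cds[1]] = stop.encode()
            else:
                utr3 = (start, start + u3)
                cds = (start + u3, start + u3 + cds_len)
                utr5 = (cds[1], end)
                stop = STOP_CODONS[int(rng.integers(3))]
                seq[cds[0] : cds[0] + 3] = reverse_complement(stop).encode()
            placed.append((start, end))
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"gene{i:04d}",
                    chrom=chrom,
                    strand=strand,
                    utr5=utr5,
                    cds=cds,
                    utr3=utr3,
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not place gene {i} without overlap after {max_tries} tries"
            )
    transcripts.sort(key=lambda t: t.start)
    return {chrom: seq.decode("ascii")}, transcripts


def _sense_to_genomic(t: TranscriptModel, seg: tuple[int, int], offset: int, length: int) -> int:
    """Genomic start of a length-`length` motif at sense-strand offset
    `offset` within segment `seg`."""
    if t.strand == "+":
        return seg[0] + offset
    return seg[1] - offset - length


def plant_motifs(
    genome: dict[str, str],
    transcripts: list[TranscriptModel],
    motifs_by_protein: dict[str, tuple[str, ...]] | None = None,
    sites_per_region: dict[str, int] | None = None,
    seed: int = 0,
    margin: int = 30,
    max_tries: int = 200,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write binding motifs into transcript sequences and return the truth table.

    sites_per_region maps region class (utr5/cds/utr3) to the number of
    sites to plant there; hosts are drawn at random, proteins and motifs
    round-robin over the configured sets. The cross-link position is a
    random T of the motif on the transcript sense strand.
    """
    motifs_by_protein = motifs_by_protein or DEFAULT_MOTIFS
    sites_per_region = sites_per_region if sites_per_region is not None else {"utr5": 2, "cds": 4, "utr3": 2}
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome))
    seq = bytearray(genome[chrom], "ascii")
    proteins = sorted(motifs_by_protein)
    sites: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    k = 0
    for region in ("utr5", "cds", "utr3"):
        for _ in range(int(sites_per_region.get(region, 0))):
            protein = proteins[k % len(proteins)]
            motif = motifs_by_protein[protein][(k // len(proteins)) % len(motifs_by_protein[protein])]
            k += 1
            dna = rna_to_dna(motif)
            t_offsets = [i for i, b in enumerate(dna) if b == "T"]
            if not t_offsets:
                raise ValueError(f"motif {motif} contains no U; cannot place a cross-link")
            for _attempt in range(max_tries):
                t = transcripts[int(rng.integers(len(transcripts)))]
                seg = getattr(t, region)
                if seg is None or seg[1] - seg[0] < len(dna):
                    continue
                offset = int(rng.integers(0, seg[1] - seg[0] - len(dna) + 1))
                gstart = _sense_to_genomic(t, seg, offset, len(dna))
                gend = gstart + len(dna)
                if any(gstart - margin < oe and os_ < gend + margin for os_, oe in occupied):
                    continue
                written = dna if t.strand == "+" else reverse_complement(dna)
                seq[gstart:gend] = written.encode()
                t_off = t_offsets[int(rng.integers(len(t_offsets)))]
                xl = gstart + t_off if t.strand == "+" else gend - 1 - t_off
                occupied.append((gstart, gend))
                sites.append(
                    PlantedSite(
                        transcript_id=t.transcript_id,
                        chrom=chrom,
                        strand=t.strand,
                        genomic_start=gstart,
                        motif=motif,
                        crosslink_position=xl,
                        protein=protein,
                        region=region,
                    )
                )
                break
            else:
                raise RuntimeError(
                    f"could not place a {motif} site in region {region} after {max_tries} tries"
                )
    return {chrom: seq.decode("ascii")}, sites


def simulate_reads(
    genome: dict[str, str],
    transcripts: list[TranscriptModel],
    sites: list[PlantedSite],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[TruthRead]]:
    """Emit (read_id, sense-strand sequence) pairs plus a per-read truth table.

    Bound reads draw a planted site uniformly and start uniformly among the
    placements that cover its cross-link position; background reads start
    uniformly within a random transcript. Any read covering a cross-link
    position of its own transcript's strand converts T>C there with
    probability tc_rate (genomically A>G on the minus strand). Sequencing
    errors are uniform substitutions at error_rate per base; each read is
    duplicated verbatim with probability duplication_rate.
    """
    rng = np.random.default_rng(config.seed)
    chrom = next(iter(genome))
    seq = genome[chrom]
    by_transcript = {t.transcript_id: t for t in transcripts}
    # cross-link positions per strand for the "any covering read" conversion rule
    xl_by_strand: dict[str, np.ndarray] = {}
    for strand in "+-":
        xl_by_strand[strand] = np.array(
            sorted(s.crosslink_position for s in sites if s.strand == strand), dtype=np.int64
        )

    reads: list[tuple[str, str]] = []
    truth: list[TruthRead] = []
    lo = max(1, config.read_length_mean - config.read_length_spread)
    hi = config.read_length_mean + config.read_length_spread

    for i in range(config.n_reads):
        length = int(rng.integers(lo, hi + 1))
        if sites and rng.random() < config.bound_fraction:
            site = sites[int(rng.integers(len(sites)))]
            t = by_transcript[site.transcript_id]
            length = min(length, t.length)
            w_lo = max(t.start, site.crosslink_position - length + 1)
            w_hi = min(t.end - length, site.crosslink_position)
            if w_hi < w_lo:  # site squeezed against a transcript edge
                w_lo = w_hi = max(t.start, min(site.crosslink_position, t.end - length))
            start = int(rng.integers(w_lo, w_hi + 1))
            origin = site.site_id
        else:
            t = transcripts[int(rng.integers(len(transcripts)))]
            length = min(length, t.length)
            start = int(rng.integers(t.start, t.end - length + 1))
            origin = "background"
        end = start + length
        genomic = seq[start:end]
        sense = genomic if t.strand == "+" else reverse_complement(genomic)
        sense_arr = bytearray(sense, "ascii")
        subs: dict[int, tuple[str, str]] = {}  # genomic pos -> (ref, alt)

        def sense_index(gpos: int) -> int:
            return gpos - start if t.strand == "+" else end - 1 - gpos

        xls = xl_by_strand[t.strand]
        if xls.size:
            j0, j1 = np.searchsorted(xls, (start, end), side="left")
            for gpos in xls[j0:j1]:
                gpos = int(gpos)
                si = sense_index(gpos)
                if sense_arr[si : si + 1] == b"T" and rng.random() < config.tc_rate:
                    sense_arr[si] = ord("C")
                    if t.strand == "+":
                        subs[gpos] = ("T", "C")
                    else:
                        subs[gpos] = ("A", "G")

        if config.error_rate > 0:
            err_mask = rng.random(length) < config.error_rate
            for si in np.nonzero(err_mask)[0]:
                si = int(si)
                current = chr(sense_arr[si])
                alt = "ACGT".replace(current, "")[int(rng.integers(3))]
                sense_arr[si] = ord(alt)
                gpos = start + si if t.strand == "+" else end - 1 - si
                g_ref = seq[gpos]
                g_alt = alt if t.strand == "+" else reverse_complement(alt)
                if g_alt == g_ref:
                    subs.pop(gpos, None)  # error reverted the base to reference
                else:
                    subs[gpos] = (g_ref, g_alt)

        read_id = f"read{i:06d}"
        final = sense_arr.decode("ascii")
        sub_tuple = tuple(Substitution(p, r, a) for p, (r, a) in sorted(subs.items()))
        reads.append((read_id, final))
        truth.append(TruthRead(read_id, chrom, start, end, t.strand, origin, sub_tuple))
        if rng.random() < config.duplication_rate:
            dup_id = f"{read_id}.dup"
            reads.append((dup_id, final))
            truth.append(TruthRead(dup_id, chrom, start, end, t.strand, origin, sub_tuple))
    return reads, truth


def write_truth_table(truth: list[TruthRead], path) -> None:
    from .io import format_substitutions

    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\torigin\tsubstitutions\n")
        for r in truth:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.origin}\t"
                f"{format_substitutions(r.substitutions)}\n"
            )


def truth_to_aligned(truth: list[TruthRead]):
    """Ground-truth reads as AlignedRead objects (bypasses the aligner, for
    isolating downstream stages against simulator truth)."""
    from .model import AlignedRead

    return [
        AlignedRead(
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            strand=r.strand,
            substitutions=r.substitutions,
            read_id=r.read_id,
        )
        for r in truth
    ]


@dataclass
class Scenario:
    """A complete synthetic dataset plus its ground truth."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    sites: list[PlantedSite]
    reads: list[tuple[str, str]]
    truth: list[TruthRead]
    config: SimulationConfig = field(default_factory=SimulationConfig)


def make_scenario(
    seed: int = 0,
    genome_length: int = 40_000,
    n_genes: int = 20,
    sites_per_region: dict[str, int] | None = None,
    motifs_by_protein: dict[str, tuple[str, ...]] | None = None,
    config: SimulationConfig | None = None,
) -> Scenario:
    """Default end-to-end scenario: genome, annotation, planted sites, reads.

    Derived seeds keep the four generation stages independent but all
    reproducible from the single top-level seed.
    """
    config = config or SimulationConfig(seed=seed * 4 + 3)
    genome = generate_genome(GenomeSpec(length=genome_length, seed=seed * 4))
    genome, transcripts = generate_annotation(genome, n_genes=n_genes, seed=seed * 4 + 1)
    genome, sites = plant_motifs(
        genome,
        transcripts,
        motifs_by_protein=motifs_by_protein,
        sites_per_region=sites_per_region,
        seed=seed * 4 + 2,
    )
    reads, truth = simulate_reads(genome, transcripts, sites, config)
    return Scenario(genome, transcripts, sites, reads, truth, config)
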