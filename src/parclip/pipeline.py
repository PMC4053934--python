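"""End-to-end orchestration: simulate -> collapse -> align -> FDR peaks ->
contigs -> motifs -> cross-linked motifs -> profiles -> summaries.

Every stage writes plain-text outputs (FASTA/FASTQ/GTF/BED/bedGraph/TSV)
into the run directory, and a JSON manifest records parameters, seeds and
per-stage record counts. Runs are fully deterministic for a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .featstats import (
    class_percentages,
    filter_intronless,
    length_comparison,
    region_assignment,
    stop_codon_overlap,
    target_table,
)
from .model import Interval
from .motifs import cross_linked_motifs, kmer_zscores, scan_motifs
from .peaks import call_peaks, coverage_track
from .profiles import (
    ProfileConfig,
    anchor_matrix,
    anchor_profile,
    bin_density,
    binding_probability,
    kmeans_rows,
    tc_percentage_profile,
    transcript_anchors,
    write_matrix_cluster3,
    write_profile_tsv,
)
from .readproc import align_unique, collapse_duplicates
from .synthetic import DEFAULT_MOTIFS, SimulationConfig, make_scenario, write_truth_table

log = logging.getLogger("parclip")

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    outdir: str = "parclip_run"
    # input paths; when None the synthetic scenario is generated
    genome_fasta: str | None = None
    annotation_gtf: str | None = None
    reads_fastq: str | None = None
    # synthetic scenario
    seed: int = 0
    genome_length: int = 40_000
    n_genes: int = 20
    sim: SimulationConfig | None = None
    # analysis parameters
    alpha: float = 0.01
    n_iter: int = 100
    max_mismatches: int = 2
    k_range: tuple[int, int] = (4, 6)
    n_shuffles: int = 100
    crosslink_flank: int = 0
    motifs_by_protein: dict = field(default_factory=lambda: {p: tuple(ms) for p, ms in DEFAULT_MOTIFS.items()})
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    kmeans_k: int = 3
    length_threshold: int = 782
    plot: bool = False

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword arguments override file values.
        Nested keys: ``sim`` maps to SimulationConfig fields, ``profile``
        to ProfileConfig fields."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("sim"), dict):
            data["sim"] = SimulationConfig(**data["sim"])
        if isinstance(data.get("profile"), dict):
            data["profile"] = ProfileConfig(**data["profile"])
        if isinstance(data.get("k_range"), list):
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all outputs under config.outdir, and return
    the manifest (also written as manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": VERSION,
        "parameters": {
            "seed": config.seed,
            "alpha": config.alpha,
            "n_iter": config.n_iter,
            "max_mismatches": config.max_mismatches,
            "k_range": list(config.k_range),
            "n_shuffles": config.n_shuffles,
            "crosslink_flank": config.crosslink_flank,
            "kmeans_k": config.kmeans_k,
            "length_threshold": config.length_threshold,
            "motifs": {p: list(ms) for p, ms in sorted(config.motifs_by_protein.items())},
        },
        "counts": {},
    }
    counts = manifest["counts"]

    # ---- stage 1: inputs (simulate or load) ---------------------------------
    if config.reads_fastq is None:
        log.info("simulating synthetic scenario (seed=%d)", config.seed)
        scenario = make_scenario(
            seed=config.seed,
            genome_length=config.genome_length,
            n_genes=config.n_genes,
            motifs_by_protein=config.motifs_by_protein,
            config=config.sim,
        )
        genome, transcripts = scenario.genome, scenario.transcripts
        raw_reads = scenario.reads
        pio.write_fasta(genome, out / "genome.fasta")
        pio.write_transcripts_gtf(transcripts, out / "annotation.gtf")
        pio.write_fastq(raw_reads, out / "reads.fastq")
        write_truth_table(scenario.truth, out / "truth.tsv")
        site_rows = [
            (
                Interval(s.chrom, s.genomic_start, s.genomic_end, s.strand),
                {"transcript_id": s.transcript_id, "motif": s.motif, "protein": s.protein,
                 "crosslink_position": s.crosslink_position, "region": s.region},
            )
            for s in scenario.sites
        ]
        pio.write_intervals_gtf(site_rows, out / "planted_sites.gtf", feature="planted_site")
        counts["planted_sites"] = len(scenario.sites)
    else:
        genome = pio.read_fasta(config.genome_fasta)
        transcripts = pio.read_transcripts_gtf(config.annotation_gtf)
        raw_reads = pio.read_fastq(config.reads_fastq)
        scenario = None
    transcripts = filter_intronless(transcripts, config.annotation_gtf)
    counts["raw_reads"] = len(raw_reads)
    counts["transcripts"] = len(transcripts)

    # ---- stage 2: collapse duplicates --------------------------------------
    collapsed = collapse_duplicates(raw_reads)
    counts["collapsed_reads"] = len(collapsed)
    log.info("collapsed %d raw reads to %d distinct sequences", len(raw_reads), len(collapsed))

    # ---- stage 3: unique alignment -----------------------------------------
    aligned, astats = align_unique(collapsed, genome, max_mismatches=config.max_mismatches)
    counts["aligned_reads"] = astats.aligned
    counts["unmapped_reads"] = astats.unmapped
    counts["multimapped_reads"] = astats.multimapped
    pio.write_reads_bed(aligned, out / "aligned_reads.bed")
    log.info("aligned %d/%d collapsed reads uniquely", astats.aligned, astats.total)

    # ---- stage 4: FDR peak calling and contigs -----------------------------
    tables, intervals, contigs = call_peaks(
        aligned, transcripts, genome, alpha=config.alpha, n_iter=config.n_iter, seed=config.seed
    )
    counts["features_with_significant_intervals"] = sum(
        1 for t in tables.values() if not t.empty and t.h_min_at(config.alpha) is not None
    )
    counts["selected_intervals"] = len(intervals)
    counts["contigs"] = len(contigs)
    with open(out / "hmin.tsv", "w") as fh:
        fh.write("feature_id\th_min\tmax_height\n")
        for fid in sorted(tables):
            t = tables[fid]
            hm = "" if t.empty else t.h_min_at(config.alpha)
            mx = 0 if t.empty else int(t.heights[-1])
            fh.write(f"{fid}\t{hm if hm is not None else '.'}\t{mx}\n")
    rows = [
        (iv, {"feature_id": c.feature_id, "h_min": int(c.coverage.min())})
        for iv, c in zip(intervals, contigs)
    ]
    pio.write_intervals_gtf(rows, out / "selected_intervals.gtf", feature="interval")
    pio.write_contigs_gtf(contigs, out / "contigs.gtf")
    pio.write_contigs_tsv(contigs, out / "contigs.tsv")
    tracks = [coverage_track(aligned, t) for t in transcripts]
    pio.write_bedgraph(tracks, out / "coverage_plus.bedgraph", "+")
    pio.write_bedgraph(tracks, out / "coverage_minus.bedgraph", "-")
    log.info("peak calling: %d contigs across %d features", len(contigs), counts["features_with_significant_intervals"])

    # ---- stage 5: motifs ----------------------------------------------------
    genome_hits = scan_motifs(genome, config.motifs_by_protein)
    identified = cross_linked_motifs(genome_hits, contigs, flank=config.crosslink_flank)
    crosslinked = [h for h in identified if h.crosslinked]
    counts["motif_hits_genome"] = len(genome_hits)
    counts["motif_hits_in_contigs"] = len(identified)
    counts["crosslinked_motifs"] = len(crosslinked)
    pio.write_motif_hits_gtf(genome_hits, out / "motifs_genome.gtf")
    pio.write_motif_hits_gtf(identified, out / "motifs_identified.gtf")
    gtf_bed_convert(out / "motifs_identified.gtf", out / "motifs_identified.bed", "gtf2bed")
    for k in range(config.k_range[0], config.k_range[1] + 1):
        stats = kmer_zscores(contigs, k, n_shuffles=config.n_shuffles, seed=config.seed + k)
        with open(out / f"kmers_k{k}.tsv", "w") as fh:
            fh.write("kmer\tcount\tz\trandom_mean\trandom_sd\n")
            for st in stats:
                fh.write(f"{st.kmer}\t{st.observed}\t{st.z:.6g}\t{st.random_mean:.6g}\t{st.random_sd:.6g}\n")
    log.info("motifs: %d genome-wide, %d in contigs, %d cross-linked", len(genome_hits), len(identified), len(crosslinked))

    # ---- stage 6: profiles --------------------------------------------------
    pc = config.profile
    all_profile = bin_density(genome_hits, transcripts, pc)
    xl_profile, xl_matrix = bin_density(crosslinked, transcripts, pc, per_gene=True)
    prob = binding_probability(xl_profile, all_profile)
    write_profile_tsv(all_profile, out / "profile_all_motifs.tsv")
    write_profile_tsv(xl_profile, out / "profile_crosslinked.tsv")
    write_profile_tsv(prob, out / "profile_binding_probability.tsv", value_name="probability")
    tss = anchor_profile(crosslinked, transcript_anchors(transcripts, "tss"), pc.tss_flank)
    stop = anchor_profile(crosslinked, transcript_anchors(transcripts, "stop_codon"), pc.tss_flank)
    pa = anchor_profile(crosslinked, transcript_anchors(transcripts, "pa_site"), pc.tss_flank)
    write_profile_tsv(tss, out / "profile_tss.tsv")
    write_profile_tsv(stop, out / "profile_stop_codon.tsv")
    write_profile_tsv(pa, out / "profile_pa_site.tsv")
    motif_lens = {h.end - h.start for h in crosslinked}
    if crosslinked and len(motif_lens) == 1:
        tcp = tc_percentage_profile(contigs, crosslinked, flank=pc.motif_flank)
        write_profile_tsv(tcp, out / "profile_tc_percentage.tsv", value_name="tc_percent")
    write_matrix_cluster3(xl_matrix, out / "gene_bin_matrix.tsv")
    tss_matrix = anchor_matrix(crosslinked, transcripts, pc.tss_flank, "tss")
    if len(xl_matrix) >= config.kmeans_k:
        labels = kmeans_rows(xl_matrix, config.kmeans_k, seed=config.seed)
        with open(out / "kmeans_labels.tsv", "w") as fh:
            fh.write("transcript_id\tcluster\n")
            for tid, lab in zip(xl_matrix.index, labels):
                fh.write(f"{tid}\t{int(lab)}\n")
        # heat-map export: rows ordered by cluster, then total mass descending
        order = sorted(
            range(len(tss_matrix)),
            key=lambda i: (int(labels[i]), -float(tss_matrix.iloc[i].sum()), tss_matrix.index[i]),
        )
        tss_matrix = tss_matrix.iloc[order]
    write_matrix_cluster3(tss_matrix, out / "tss_anchor_matrix.tsv")

    # ---- stage 7: feature statistics ----------------------------------------
    summaries = class_percentages(genome_hits, identified, transcripts)
    with open(out / "class_summary.tsv", "w") as fh:
        fh.write(
            "feature_class\tgenes_total\tgenes_with_motif\tgenes_with_crosslinked_motif\t"
            "pct_genes_with_motif\tpct_genes_with_crosslinked_motif\tpct_hits_crosslinked\n"
        )
        for s in summaries:
            fh.write(
                f"{s.feature_class}\t{s.genes_total}\t{s.genes_with_motif}\t{s.genes_with_crosslinked_motif}\t"
                f"{s.pct_genes_with_motif:.4f}\t{s.pct_genes_with_crosslinked_motif:.4f}\t{s.pct_hits_crosslinked:.4f}\n"
            )
    dist = region_assignment(crosslinked, transcripts)
    with open(out / "region_distribution.tsv", "w") as fh:
        fh.write("utr5\tcds\tutr3\tno_utr_fallback\tunassigned\n")
        fh.write(f"{dist.utr5}\t{dist.cds}\t{dist.utr3}\t{dist.no_utr_fallback}\t{dist.unassigned}\n")
    counts["crosslinked_in_utr5"] = dist.utr5
    counts["crosslinked_in_cds"] = dist.cds
    counts["crosslinked_in_utr3"] = dist.utr3
    nrd1_xl = [h for h in crosslinked if h.protein == "Nrd1"]
    manifest["stop_codon_overlap_fraction"] = stop_codon_overlap(nrd1_xl, transcripts)
    table = target_table(transcripts, identified)
    table.to_csv(out / "target_table.tsv", sep="\t", index=False)
    counts["target_transcripts"] = int((table["n_crosslinked"] > 0).sum())
    targets = table[table["n_crosslinked"] > 0]
    if len(targets) > 0:
        lc = length_comparison(
            targets["length"], [t.length for t in transcripts], threshold=config.length_threshold
        )
        manifest["length_ks"] = {
            "d_statistic": lc.d_statistic,
            "p_value": lc.p_value,
            "fraction_above_threshold": lc.fraction_above,
            "threshold": lc.threshold,
        }

    if config.plot:
        _render_plots(out, prob, tss)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _render_plots(outdir: Path, prob, tss) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6))
    ax1.plot(prob.values)
    ax1.set_xlabel("bin (5'UTR | CDS | 3'UTR)")
    ax1.set_ylabel("binding probability")
    for x in prob.boundaries.values():
        ax1.axvline(x, color="grey", lw=0.5)
    flank = tss.boundaries.get("anchor", len(tss.values) // 2)
    ax2.plot(np.arange(len(tss.values)) - flank, tss.values)
    ax2.set_xlabel("distance from TSS (nt)")
    ax2.set_ylabel("cross-linked motif nucleotides")
    fig.tight_layout()
    fig.savefig(outdir / "profiles.png", dpi=120)
    plt.close(fig)


# --------------------------------------------------------- GTF <-> BED

def gtf_bed_convert(in_path, out_path, direction: str) -> int:
    """Coordinate-convention conversion between GTF (1-based inclusive) and
    BED (0-based half-open). Returns the number of records converted."""
    n = 0
    with open(in_path) as src, open(out_path, "w") as dst:
        for lineno, line in enumerate(src, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if direction == "gtf2bed":
                    chrom, _source, feature, start, end, score, strand = fields[:7]
                    dst.write(f"{chrom}\t{int(start) - 1}\t{end}\t{feature}\t{score}\t{strand}\n")
                elif direction == "bed2gtf":
                    chrom, start, end, name, score, strand = fields[:6]
                    dst.write(
                        f"{chrom}\tparclip\t{name}\t{int(start) + 1}\t{end}\t{score}\t{strand}\t.\t.\n"
                    )
                else:
                    raise ValueError(f"unknown direction: {direction}")
            except (ValueError, IndexError) as exc:
                if "unknown direction" in str(exc):
                    raise
                raise ValueError(f"malformed line {lineno} in {in_path}: {line!r}") from exc
            n += 1
    return n
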