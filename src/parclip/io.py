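"""Plain-text I/O: FASTA/FASTQ (Biopython), GTF, BED6+substitutions, bedGraph.

The GTF dialect stores each transcript as 5UTR/CDS/3UTR feature lines with
``gene_id``/``transcript_id`` attributes (1-based inclusive coordinates, as
GTF requires). Aligned reads travel as BED6 plus a 7th column holding
substitutions as ``pos:ref>alt;...`` with 0-based genomic positions; ``.``
means none. The BED score column carries read multiplicity.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    Contig,
    CoverageTrack,
    Interval,
    MotifHit,
    Substitution,
    TranscriptModel,
)


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs with a constant placeholder quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path_or_handle) -> list[tuple[str, str]]:
    """Return (read_id, sequence) pairs; malformed records raise ValueError
    naming the offending record."""
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle)
    out = []
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            out.append((rec.id, str(rec.seq).upper()))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {len(out) + 1}: {exc}") from exc
    finally:
        if handle is not path_or_handle:
            handle.close()
    return out


# ----------------------------------------------------------------------- GTF

_SEGMENT_FEATURES = {"5UTR": "utr5", "CDS": "cds", "3UTR": "utr3"}
_SEGMENT_NAMES = {v: k for k, v in _SEGMENT_FEATURES.items()}


def _gtf_attrs(pairs: dict) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs.items())


def _parse_gtf_attrs(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_transcripts_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for t in transcripts:
            for name in ("utr5", "cds", "utr3"):
                seg = getattr(t, name)
                if seg is None:
                    continue
                attrs = _gtf_attrs(
                    {
                        "gene_id": t.transcript_id,
                        "transcript_id": t.transcript_id,
                        "feature_class": t.feature_class,
                    }
                )
                fh.write(
                    f"{t.chrom}\tparclip\t{_SEGMENT_NAMES[name]}\t{seg[0] + 1}\t{seg[1]}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_transcripts_gtf(path) -> list[TranscriptModel]:
    segments: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: {line!r}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields[:9]
            if feature not in _SEGMENT_FEATURES:
                continue
            attrs = _parse_gtf_attrs(attr_text)
            tid = attrs["transcript_id"]
            rec = segments.setdefault(
                tid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "feature_class": attrs.get("feature_class", "mRNA"),
                    "utr5": None,
                    "cds": None,
                    "utr3": None,
                },
            )
            rec[_SEGMENT_FEATURES[feature]] = (int(start) - 1, int(end))
    out = []
    for tid, rec in segments.items():
        if rec["cds"] is None:
            raise ValueError(f"transcript {tid} has no CDS segment")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                utr5=rec["utr5"],
                cds=rec["cds"],
                utr3=rec["utr3"],
                feature_class=rec["feature_class"],
            )
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_intervals_gtf(rows: Sequence[tuple[Interval, dict]], path, feature: str = "interval") -> None:
    """Emit (interval, attributes) rows as GTF."""
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for iv, attrs in rows:
            fh.write(
                f"{iv.chrom}\tparclip\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{_gtf_attrs(attrs)}\n"
            )


def write_motif_hits_gtf(hits: Sequence[MotifHit], path) -> None:
    rows = [
        (
            hit.interval(),
            {
                "protein": hit.protein,
                "motif": hit.motif,
                "crosslinked": str(hit.crosslinked).lower(),
                "host_feature": hit.host_feature or ".",
            },
        )
        for hit in hits
    ]
    write_intervals_gtf(rows, path, feature="motif")


def write_contigs_gtf(contigs: Sequence[Contig], path) -> None:
    rows = [
        (c.interval(), {"feature_id": c.feature_id, "tc_total": int(c.tc_count.sum())})
        for c in contigs
    ]
    write_intervals_gtf(rows, path, feature="contig")


def write_contigs_tsv(contigs: Sequence[Contig], path) -> None:
    """Full contig records including per-position arrays (comma-joined), so
    downstream stages can run from files."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tfeature_id\tsequence\tcoverage\ttc_count\tt_coverage\n")
        for c in contigs:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.feature_id or '.'}\t{c.sequence}\t"
                f"{','.join(map(str, c.coverage.tolist()))}\t"
                f"{','.join(map(str, c.tc_count.tolist()))}\t"
                f"{','.join(map(str, c.t_coverage.tolist()))}\n"
            )


def read_contigs_tsv(path) -> list[Contig]:
    import numpy as np

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"unexpected contig table header: {header!r}")
        for line in fh:
            chrom, start, end, strand, fid, seq, cov, tc, tcov = line.rstrip("\n").split("\t")
            out.append(
                Contig(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    coverage=np.array([int(x) for x in cov.split(",")]),
                    tc_count=np.array([int(x) for x in tc.split(",")]),
                    t_coverage=np.array([int(x) for x in tcov.split(",")]),
                    feature_id="" if fid == "." else fid,
                    sequence=seq,
                )
            )
    return out


def read_motif_hits_gtf(path) -> list[MotifHit]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = _parse_gtf_attrs(fields[8])
            out.append(
                MotifHit(
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    motif=attrs["motif"],
                    protein=attrs["protein"],
                    crosslinked=attrs.get("crosslinked", "false") == "true",
                    host_feature=None if attrs.get("host_feature", ".") == "." else attrs["host_feature"],
                )
            )
    return out


# ------------------------------------------------------- BED / bedGraph

def format_substitutions(subs: Sequence[Substitution]) -> str:
    if not subs:
        return "."
    return ";".join(f"{s.pos}:{s.ref}>{s.alt}" for s in subs)


def parse_substitutions(text: str) -> tuple[Substitution, ...]:
    text = text.strip()
    if text in (".", ""):
        return ()
    subs = []
    for chunk in text.split(";"):
        pos_part, _, change = chunk.partition(":")
        ref, _, alt = change.partition(">")
        subs.append(Substitution(int(pos_part), ref, alt))
    return tuple(subs)


def write_reads_bed(reads: Sequence[AlignedRead], path) -> None:
    """BED6 + substitution column; score column = multiplicity."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id or '.'}\t{r.multiplicity}\t"
                f"{r.strand}\t{format_substitutions(r.substitutions)}\n"
            )


def read_reads_bed(path) -> list[AlignedRead]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            chrom, start, end, name, score, strand = fields[:6]
            subs = parse_substitutions(fields[6]) if len(fields) > 6 else ()
            out.append(
                AlignedRead(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    substitutions=subs,
                    multiplicity=int(score) if score != "." else 1,
                    read_id="" if name == "." else name,
                )
            )
    return out


def write_bedgraph(tracks: Sequence[CoverageTrack], path, strand: str) -> None:
    """Run-length-compressed bedGraph for one strand."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="coverage {strand}"\n')
        for track in tracks:
            if track.strand != strand:
                continue
            heights = track.heights
            run_start = 0
            for i in range(1, len(heights) + 1):
                if i == len(heights) or heights[i] != heights[run_start]:
                    h = int(heights[run_start])
                    if h != 0:
                        fh.write(
                            f"{track.chrom}\t{track.start + run_start}\t{track.start + i}\t{h}\n"
                        )
                    run_start = i


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), float(value)))
    return out
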