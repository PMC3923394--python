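"""Readers and writers for the standard formats the pipeline consumes.

Internally everything is 1-based fully closed (GFF3/SAM convention).  BED is
0-based half-open on disk; the conversion happens here and nowhere else:
``internal_start = bed_start + 1``, ``internal_end = bed_end``.

Chromosome names are matched by exact string equality throughout; no
"chr"-prefix aliasing is attempted.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import AlignedRead, GeneModel, GenomicInterval, Peak, Strand, sort_key


class ParseError(ValueError):
    """A malformed record; the message names the file and line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Dict[str, str], path: str, line_width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED6 (reads, planted sites, generic stranded intervals)

def _parse_bed_line(line: str, path: str, lineno: int, min_fields: int) -> List[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise ParseError(
            f"{path}:{lineno}: expected >= {min_fields} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def read_reads_bed(path: str) -> List[AlignedRead]:
    """Read aligned reads from BED6 (name/score ignored, strand required)."""
    reads: List[AlignedRead] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_line(line, path, lineno, 6)
            chrom, bed_start, bed_end = fields[0], fields[1], fields[2]
            try:
                start = int(bed_start) + 1
                end = int(bed_end)
                interval = GenomicInterval(chrom, start, end)
                strand = Strand.from_symbol(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            reads.append(AlignedRead(interval, strand))
    return reads


def write_reads_bed(reads: Sequence[AlignedRead], path: str, name_prefix: str = "read") -> None:
    ordered = sorted(reads, key=lambda r: sort_key(r.interval))
    with open(path, "w") as handle:
        for i, read in enumerate(ordered, start=1):
            iv = read.interval
            handle.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name_prefix}{i}\t0\t"
                f"{read.strand.value}\n"
            )


# ---------------------------------------------------------------------------
# SAM (minimal field subset: chrom, pos, span, strand flag)

def read_reads_sam(path: str) -> List[AlignedRead]:
    """Read aligned reads from SAM.

    Only chromosome, 1-based position, aligned span and the reverse-strand
    flag are consumed; mapping quality and mismatch tags are upstream
    concerns and are ignored.  Unmapped records are skipped.
    """
    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            start = rec.reference_start + 1  # pysam is 0-based
            end = rec.reference_end if rec.reference_end is not None else (
                start + rec.query_length - 1
            )
            strand = Strand.REVERSE if rec.is_reverse else Strand.FORWARD
            reads.append(AlignedRead(GenomicInterval(rec.reference_name, start, end), strand))
    return reads


# ---------------------------------------------------------------------------
# Peaks (BED6 + TSV sidecar with summit)

def write_peaks(peaks: Sequence[Peak], bed_path: str, tsv_path: str | None = None) -> None:
    """Write peaks as BED6 (score rounded to 1 decimal, strand '.') and,
    optionally, a TSV carrying exact scores and summits."""
    ordered = sorted(peaks, key=lambda p: sort_key(p.interval))
    with open(bed_path, "w") as handle:
        for i, peak in enumerate(ordered, start=1):
            iv = peak.interval
            handle.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tpeak{i}\t{peak.score:.1f}\t.\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as handle:
            handle.write("chrom\tstart\tend\tlength\tscore\tsummit\n")
            for peak in ordered:
                iv = peak.interval
                summit = peak.summit if peak.summit is not None else ""
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.length}\t"
                    f"{peak.score}\t{summit}\n"
                )


def read_peaks_bed(path: str) -> List[Peak]:
    peaks: List[Peak] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_line(line, path, lineno, 3)
            try:
                interval = GenomicInterval(fields[0], int(fields[1]) + 1, int(fields[2]))
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(Peak(interval, score))
    return peaks


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_annotation(path: str) -> List[GeneModel]:
    """Read gene models from GFF3.

    ``gene`` features are required; ``exon`` children (linked via Parent,
    possibly through an mRNA level) are attached when present.  GFF3 is
    1-based inclusive, matching the internal convention, so coordinates pass
    through unchanged.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            {
                (exon.seqid, exon.start, exon.end)
                for exon in db.children(feat, featuretype="exon")
            }
        )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                interval=GenomicInterval(feat.seqid, feat.start, feat.end),
                strand=Strand.from_symbol(feat.strand),
                exons=tuple(GenomicInterval(c, s, e) for c, s, e in exons),
            )
        )
    return genes


def write_annotation(genes: Sequence[GeneModel], path: str, source: str = "chipscape") -> None:
    ordered = sorted(genes, key=lambda g: sort_key(g.interval))
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in ordered:
            iv = gene.interval
            handle.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start}\t{iv.end}\t.\t"
                f"{gene.strand.value}\t.\tID={gene.gene_id}\n"
            )
            for j, exon in enumerate(gene.exons, start=1):
                handle.write(
                    f"{exon.chrom}\t{source}\texon\t{exon.start}\t{exon.end}\t.\t"
                    f"{gene.strand.value}\t.\tID={gene.gene_id}.exon{j};"
                    f"Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Chromosome lengths (samtools faidx style: name <TAB> length ...)

def read_chrom_lengths(path: str) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return lengths
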