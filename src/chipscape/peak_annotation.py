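"""Assignment of peaks to genes and genic zones.

A gene's "genic region" spans from 3 kb upstream of the transcription start
site to 1 kb downstream of the end of transcription, strand-aware.  Inside
it, three abutting zones partition the region: the promoter (the 3 kb
upstream of the TSS), the gene body (TSS..TES, introns included), and the
downstream flank (1 kb past the TES).  A peak is classified by a single
anchor point — its summit when known, otherwise the interval midpoint — so
the four labels (the three zones plus intergenic) form a partition and the
reported percentages sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core.intervals import GeneModel, GenomicInterval, Peak, Strand

ZONES: Tuple[str, str, str] = ("promoter", "gene_body", "downstream")
INTERGENIC = "intergenic"

DEFAULT_UPSTREAM = 3_000
DEFAULT_DOWNSTREAM = 1_000


@dataclass(frozen=True)
class GenicRegion:
    """Promoter / body / downstream geometry for one gene.

    The three intervals abut with no gaps or overlaps; promoter and
    downstream have their nominal lengths (3,000 and 1,000 bp by default)
    unless clamped at a chromosome end.
    """

    gene_id: str
    strand: Strand
    tss: int
    promoter: GenomicInterval
    body: GenomicInterval
    downstream: GenomicInterval

    @property
    def span(self) -> GenomicInterval:
        start = min(self.promoter.start, self.body.start, self.downstream.start)
        end = max(self.promoter.end, self.body.end, self.downstream.end)
        return GenomicInterval(self.body.chrom, start, end)

    def zone_of(self, chrom: str, pos: int) -> Optional[str]:
        if self.promoter.contains_position(chrom, pos):
            return "promoter"
        if self.body.contains_position(chrom, pos):
            return "gene_body"
        if self.downstream.contains_position(chrom, pos):
            return "downstream"
        return None


@dataclass(frozen=True)
class PeakAnnotation:
    """A peak with its zone label; ``gene_id`` is absent iff intergenic."""

    peak: Peak
    zone: str
    gene_id: Optional[str]
    anchor: int

    def __post_init__(self) -> None:
        if (self.zone == INTERGENIC) != (self.gene_id is None):
            raise ValueError("gene_id must be absent exactly when intergenic")


def genic_region(
    gene: GeneModel,
    chrom_lengths: Dict[str, int],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> GenicRegion:
    """Compute the strand-aware promoter/body/downstream partition for a
    gene, clamping at chromosome boundaries."""
    chrom = gene.interval.chrom
    if chrom not in chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = chrom_lengths[chrom]
    s, e = gene.interval.start, gene.interval.end

    def flank(raw_start: int, raw_end: int) -> Optional[GenomicInterval]:
        start, end = max(1, raw_start), min(length, raw_end)
        return GenomicInterval(chrom, start, end) if start <= end else None

    if gene.strand is Strand.FORWARD:
        prom = flank(s - upstream, s - 1)
        down = flank(e + 1, e + downstream)
    else:
        prom = flank(e + 1, e + upstream)
        down = flank(s - downstream, s - 1)
    body = GenomicInterval(chrom, s, e)
    # a gene flush against a chromosome end has no room for a flank at all
    if prom is None or down is None:
        raise ValueError(
            f"gene {gene.gene_id} touches a chromosome end; a flank would be empty"
        )
    return GenicRegion(gene.gene_id, gene.strand, gene.tss, prom, body, down)


def classify_peak(peak: Peak, regions: Sequence[GenicRegion]) -> PeakAnnotation:
    """Classify a peak by its anchor point (summit, else midpoint).

    When the anchor lies inside the genic regions of several genes, the gene
    whose TSS is nearest wins; exact ties go to the lexicographically
    smallest gene_id.
    """
    anchor = peak.anchor
    chrom = peak.interval.chrom
    candidates: List[Tuple[int, str, str]] = []
    for region in regions:
        zone = region.zone_of(chrom, anchor)
        if zone is not None:
            candidates.append((abs(anchor - region.tss), region.gene_id, zone))
    if not candidates:
        return PeakAnnotation(peak, INTERGENIC, None, anchor)
    _, gene_id, zone = min(candidates)
    return PeakAnnotation(peak, zone, gene_id, anchor)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    chrom_lengths: Dict[str, int],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> List[PeakAnnotation]:
    regions = [genic_region(g, chrom_lengths, upstream, downstream) for g in genes]
    return [classify_peak(p, regions) for p in peaks]


@dataclass(frozen=True)
class DistributionSummary:
    """Genome-wide peak distribution: genic fraction, and among-genic
    fractions per zone (None when no peak is genic)."""

    n_peaks: int
    n_genic: int
    fraction_genic: float
    zone_fractions: Optional[Dict[str, float]]  # among genic peaks; sums to 1

    def zone_percent(self, zone: str) -> Optional[int]:
        """Zone share among genic peaks, rounded to an integer percent."""
        if self.zone_fractions is None:
            return None
        return round(100 * self.zone_fractions[zone])

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_genic": self.n_genic,
            "fraction_genic": self.fraction_genic,
            "zone_fractions": self.zone_fractions,
            "zone_percents": (
                {z: self.zone_percent(z) for z in ZONES}
                if self.zone_fractions is not None
                else None
            ),
        }


def summarize_distribution(annotations: Sequence[PeakAnnotation]) -> DistributionSummary:
    """Summarise annotations into genic fraction and among-genic zone split."""
    if not annotations:
        raise ValueError("cannot summarise an empty annotation list")
    n = len(annotations)
    counts = {z: 0 for z in ZONES}
    for ann in annotations:
        if ann.zone != INTERGENIC:
            counts[ann.zone] += 1
    n_genic = sum(counts.values())
    zone_fractions = (
        {z: counts[z] / n_genic for z in ZONES} if n_genic > 0 else None
    )
    return DistributionSummary(n, n_genic, n_genic / n, zone_fractions)


def write_annotations_tsv(
    annotations: Sequence[PeakAnnotation],
    regions_by_gene: Dict[str, GenicRegion],
    path: str,
) -> None:
    ordered = sorted(
        annotations, key=lambda a: (a.peak.interval.chrom, a.peak.interval.start)
    )
    with open(path, "w") as handle:
        handle.write("chrom\tstart\tend\tscore\tzone\tgene_id\tanchor\tdistance_to_tss\n")
        for ann in ordered:
            iv = ann.peak.interval
            if ann.gene_id is not None:
                dist = ann.anchor - regions_by_gene[ann.gene_id].tss
                gene_id = ann.gene_id
            else:
                dist, gene_id = "", ""
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.peak.score}\t{ann.zone}\t"
                f"{gene_id}\t{ann.anchor}\t{dist}\n"
            )
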