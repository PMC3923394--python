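"""Average binding-distribution profiles over gene zones.

For one zone (promoter, gene body or downstream flank) the procedure is:
pick the genes whose coverage falls mainly in that zone; split each selected
gene's zone into 100 consecutive near-equal segments; count, per segment,
the extended reads overlapping it (5'→3' in gene orientation, so profiles of
reverse-strand genes are flipped); rescale each gene's vector to its own
maximum segment count; and average the normalised vectors element-wise
across genes.  The result shows where within the zone binding concentrates,
independent of per-gene coverage depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core.intervals import GenomicInterval, Strand
from .peak_annotation import ZONES, GenicRegion

logger = logging.getLogger(__name__)

DEFAULT_SEGMENTS = 100
DEFAULT_MAJORITY = 0.5


@dataclass(frozen=True)
class MetageneProfile:
    """Averaged normalised coverage over ``n_segments`` consecutive slices of
    one zone, with the number of genes that contributed."""

    zone: str
    values: np.ndarray  # length n_segments, each in [0, 1]
    n_genes: int

    @property
    def n_segments(self) -> int:
        return len(self.values)


def segment_bounds(length: int, n_segments: int = DEFAULT_SEGMENTS) -> List[Tuple[int, int]]:
    """Split ``length`` bases into ``n_segments`` consecutive slices as
    0-based offset pairs ``(begin, end_exclusive)``.

    The first ``length mod n_segments`` segments carry one extra base.  For
    zones shorter than ``n_segments`` the trailing segments are empty
    (zero-width) slices.
    """
    base, extra = divmod(length, n_segments)
    bounds = []
    cursor = 0
    for k in range(n_segments):
        width = base + (1 if k < extra else 0)
        bounds.append((cursor, cursor + width))
        cursor += width
    return bounds


def gene_profile(
    zone_interval: GenomicInterval,
    gene_strand: Strand,
    extended_reads: Iterable[GenomicInterval],
    n_segments: int = DEFAULT_SEGMENTS,
) -> np.ndarray:
    """Raw per-segment read counts for one gene's zone, 5'→3' in gene
    orientation.  A read increments every segment it overlaps."""
    length = zone_interval.length
    if length < n_segments:
        logger.debug(
            "zone %s shorter than %d bp; some segments are empty",
            zone_interval, n_segments,
        )
    bounds = segment_bounds(length, n_segments)
    counts = np.zeros(n_segments, dtype=np.int64)
    # per-read overlap against segment offsets within the zone
    starts = np.array([b for b, _ in bounds])
    ends = np.array([e for _, e in bounds])  # exclusive
    for read in extended_reads:
        if read.chrom != zone_interval.chrom:
            continue
        lo = max(read.start, zone_interval.start) - zone_interval.start
        hi = min(read.end, zone_interval.end) - zone_interval.start + 1  # exclusive
        if lo >= hi:
            continue
        counts += (starts < hi) & (ends > lo)
    if gene_strand is Strand.REVERSE:
        counts = counts[::-1].copy()
    return counts


def normalize_gene_profile(raw: np.ndarray) -> Optional[np.ndarray]:
    """Scale a raw count vector to its own maximum (result max = 1).

    An all-zero vector cannot be normalised; the gene is skipped (returns
    None) with a logged warning rather than producing NaNs.
    """
    raw = np.asarray(raw, dtype=float)
    peak = raw.max()
    if peak <= 0:
        logger.warning("all-zero profile; gene skipped from the average")
        return None
    return raw / peak


def average_profiles(
    normalized: Sequence[np.ndarray], zone: str
) -> MetageneProfile:
    """Element-wise arithmetic mean of per-gene normalised vectors
    (equal gene weighting)."""
    if not normalized:
        raise ValueError("no gene profiles to average")
    stacked = np.vstack(normalized)
    return MetageneProfile(zone, stacked.mean(axis=0), len(normalized))


def zone_read_totals(
    regions: Sequence[GenicRegion],
    extended_reads: Sequence[GenomicInterval],
) -> Dict[str, Dict[str, int]]:
    """Per gene, the number of extended reads overlapping each zone.

    A read overlapping several zones (or several genes) counts in each; the
    totals are a coverage-attribution used only for gene selection.
    """
    totals: Dict[str, Dict[str, int]] = {
        r.gene_id: {z: 0 for z in ZONES} for r in regions
    }
    for region in regions:
        zones = {
            "promoter": region.promoter,
            "gene_body": region.body,
            "downstream": region.downstream,
        }
        for zone, ziv in zones.items():
            totals[region.gene_id][zone] = sum(
                1 for read in extended_reads if read.overlaps(ziv)
            )
    return totals


def select_genes_for_zone(
    totals: Mapping[str, Mapping[str, int]],
    zone: str,
    majority_threshold: float = DEFAULT_MAJORITY,
) -> List[str]:
    """Genes whose genic-region coverage falls mainly (> threshold) in the
    requested zone; zero-coverage genes are excluded from every zone."""
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    selected = []
    for gene_id in sorted(totals):
        per_zone = totals[gene_id]
        total = sum(per_zone.values())
        if total > 0 and per_zone[zone] / total > majority_threshold:
            selected.append(gene_id)
    return selected


def compute_zone_profile(
    regions: Sequence[GenicRegion],
    extended_reads: Sequence[GenomicInterval],
    zone: str,
    n_segments: int = DEFAULT_SEGMENTS,
    majority_threshold: float = DEFAULT_MAJORITY,
) -> Optional[MetageneProfile]:
    """Full per-zone procedure: select genes, profile, normalise, average.

    Returns None when no gene qualifies for the zone.
    """
    totals = zone_read_totals(regions, extended_reads)
    chosen = select_genes_for_zone(totals, zone, majority_threshold)
    by_id = {r.gene_id: r for r in regions}
    vectors = []
    for gene_id in chosen:
        region = by_id[gene_id]
        ziv = {"promoter": region.promoter, "gene_body": region.body,
               "downstream": region.downstream}[zone]
        raw = gene_profile(ziv, region.strand, extended_reads, n_segments)
        norm = normalize_gene_profile(raw)
        if norm is not None:
            vectors.append(norm)
    if not vectors:
        return None
    return average_profiles(vectors, zone)


def write_profile_tsv(profile: MetageneProfile, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("segment\tmean_normalized_value\tn_genes\n")
        for k, value in enumerate(profile.values, start=1):
            handle.write(f"{k}\t{value:.6f}\t{profile.n_genes}\n")
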