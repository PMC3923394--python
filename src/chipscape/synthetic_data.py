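"""Seeded generator for miniature ChIP-seq datasets.

The generator emulates the experimental situation the downstream analysis
assumes: a genome of known base composition (default 33.2% GC, the tomato
genome value), stranded gene models with exon structure, transcription-factor
binding sites matching a degenerate consensus planted at known genic zones,
and single-end sequencing reads derived from ~400 bp chromatin fragments read
as ~51 nt tags — the immunoprecipitated sample enriched at the planted sites,
the input control uniform background only.

Every function is deterministic given its seed; all randomness flows through
``numpy.random.Generator`` streams.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core.intervals import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    Peak,
    Strand,
)
from .core import io as core_io
from .composition import CompositionModel
from .motif_stats import compile_pattern, reverse_complement
from .peak_annotation import ZONES, GenicRegion, genic_region

DEFAULT_CHROM = "chr1"

#: zone plan used by the default simulation: 10 planted sites across zones
DEFAULT_SITE_PLAN: Dict[str, int] = {
    "promoter": 4,
    "gene_body": 3,
    "downstream": 1,
    "intergenic": 2,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated ChIP experiment.

    Defaults mirror the experimental design: ~400 bp sonicated fragments
    sequenced as 51 nt single-end reads over a 33.2% GC genome.
    ``enrichment`` is the expected number of immunoprecipitated fragments per
    planted site; ``background_depth`` is expected background fragments per
    base pair.
    """

    genome_length: int = 100_000
    n_genes: int = 20
    fragment_length: int = 400
    read_length: int = 51
    enrichment: float = 50.0
    background_depth: float = 0.01
    gc_fraction: float = 0.332
    pattern: str = "WRGCCCA"
    site_plan: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PLAN)
    )
    gene_length_range: Tuple[int, int] = (400, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        for name in ("genome_length", "n_genes", "fragment_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enrichment < 0 or self.background_depth < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted consensus occurrence."""

    interval: GenomicInterval
    zone_label: str
    gene_id: Optional[str]
    strand: Strand


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genome

def generate_genome(length: int, composition: CompositionModel, seed) -> str:
    """Draw ``length`` i.i.d. bases from the composition model."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = _as_rng(seed)
    probs = composition.base_probabilities
    bases = np.frombuffer(b"ACGT", dtype="S1")
    draws = rng.choice(4, size=length, p=[probs["A"], probs["C"], probs["G"], probs["T"]])
    return bases[draws].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Gene models

class PackingError(ValueError):
    """Requested genes cannot be placed on the genome without overlap."""


def generate_gene_models(
    genome_length: int,
    n_genes: int,
    length_range: Tuple[int, int] = (400, 800),
    seed=0,
    *,
    chrom: str = DEFAULT_CHROM,
    upstream: int = 3_000,
    downstream: int = 1_000,
    max_exons: int = 5,
) -> List[GeneModel]:
    """Place stranded, non-overlapping genes whose genic regions
    (upstream promoter .. downstream flank) are also pairwise disjoint.

    Each gene carries 1–5 exons.  Raises :class:`PackingError` when the
    requested genes cannot fit; silent truncation is never performed.
    """
    rng = _as_rng(seed)
    lo, hi = length_range
    if lo < max_exons * 2 or hi < lo:
        raise ValueError(f"invalid gene length range {length_range}")
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    flank = upstream + downstream
    slots = lengths + flank
    total = int(slots.sum())
    if total > genome_length:
        raise PackingError(
            f"{n_genes} genes with genic regions need {total} bp "
            f"but the genome is {genome_length} bp"
        )
    # distribute the leftover space as random gaps before/between/after slots
    leftover = genome_length - total
    gaps = rng.multinomial(leftover, [1.0 / (n_genes + 1)] * (n_genes + 1))
    genes: List[GeneModel] = []
    cursor = 1
    for i in range(n_genes):
        cursor += int(gaps[i])
        strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
        # orient the slot so the 3 kb promoter side faces the TSS
        margin_left = upstream if strand is Strand.FORWARD else downstream
        start = cursor + margin_left
        end = start + int(lengths[i]) - 1
        exons = _random_exons(chrom, start, end, rng, max_exons)
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:03d}",
                interval=GenomicInterval(chrom, start, end),
                strand=strand,
                exons=exons,
            )
        )
        cursor += int(slots[i])
    return genes


def _random_exons(
    chrom: str, start: int, end: int, rng: np.random.Generator, max_exons: int
) -> Tuple[GenomicInterval, ...]:
    length = end - start + 1
    n_exons = int(rng.integers(1, max_exons + 1))
    if n_exons == 1:
        return (GenomicInterval(chrom, start, end),)
    # 2*n_exons - 2 interior cut points delimit alternating exons/introns
    n_cuts = 2 * n_exons - 2
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
    bounds = [0, *cuts.tolist(), length]
    exons = []
    for k in range(n_exons):
        seg_start = start + bounds[2 * k]
        seg_end = start + bounds[2 * k + 1] - 1
        exons.append(GenomicInterval(chrom, seg_start, seg_end))
    return tuple(exons)


# ---------------------------------------------------------------------------
# Site planting

class PlantingError(ValueError):
    """Not enough room to plant the requested sites."""


def plant_sites(
    genome: str,
    genes: Sequence[GeneModel],
    pattern: str,
    plan: Mapping[str, int],
    seed=0,
    *,
    chrom: str = DEFAULT_CHROM,
    upstream: int = 3_000,
    downstream: int = 1_000,
    placement: str = "uniform",
    max_tries: int = 200,
) -> Tuple[str, List[PlantedSite]]:
    """Overwrite genome positions with concrete expansions of ``pattern``.

    ``plan`` maps zone labels (promoter / gene_body / downstream /
    intergenic) to site counts.  ``placement`` is "uniform" (anywhere inside
    the zone) or "center" (at the zone midpoint, one site per gene).  Sites
    never overlap one another.  Reverse-strand sites are written as the
    reverse complement on the forward genome string.
    """
    rng = _as_rng(seed)
    compiled = compile_pattern(pattern)
    motif_len = compiled.length
    genome_len = len(genome)
    chrom_lengths = {chrom: genome_len}
    regions = [genic_region(g, chrom_lengths, upstream=upstream, downstream=downstream)
               for g in genes]
    zone_slots: Dict[str, List[Tuple[Optional[str], GenomicInterval]]] = {
        z: [] for z in ZONES
    }
    for region in regions:
        zone_slots["promoter"].append((region.gene_id, region.promoter))
        zone_slots["gene_body"].append((region.gene_id, region.body))
        zone_slots["downstream"].append((region.gene_id, region.downstream))

    seq = bytearray(genome.encode("ascii"))
    planted: List[PlantedSite] = []
    occupied: List[GenomicInterval] = []

    def overlaps_existing(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(p) for p in occupied)

    for zone in sorted(plan):
        count = plan[zone]
        if zone not in ZONES and zone != "intergenic":
            raise ValueError(f"unknown zone label {zone!r}")
        for _ in range(count):
            site = None
            for _try in range(max_tries):
                if zone == "intergenic":
                    start = int(rng.integers(1, genome_len - motif_len + 2))
                    iv = GenomicInterval(chrom, start, start + motif_len - 1)
                    if any(iv.overlaps(r.span) for r in regions):
                        continue
                    gene_id = None
                else:
                    gene_id, zone_iv = zone_slots[zone][
                        int(rng.integers(0, len(zone_slots[zone])))
                    ]
                    if zone_iv.length < motif_len:
                        continue
                    if placement == "center":
                        start = zone_iv.midpoint - motif_len // 2
                    else:
                        start = int(
                            rng.integers(zone_iv.start, zone_iv.end - motif_len + 2)
                        )
                    iv = GenomicInterval(chrom, start, start + motif_len - 1)
                    if not (zone_iv.start <= iv.start and iv.end <= zone_iv.end):
                        continue
                if overlaps_existing(iv):
                    continue
                site = iv, gene_id
                break
            if site is None:
                raise PlantingError(
                    f"could not place a {zone} site after {max_tries} attempts"
                )
            iv, gene_id = site
            strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            concrete = "".join(
                bases[int(rng.integers(0, len(bases)))]
                for bases in compiled.position_sets
            )
            written = concrete if strand is Strand.FORWARD else reverse_complement(concrete)
            seq[iv.start - 1 : iv.end] = written.encode("ascii")
            occupied.append(iv)
            planted.append(PlantedSite(iv, zone, gene_id, strand))
    return seq.decode("ascii"), planted


# ---------------------------------------------------------------------------
# Read simulation

def _fragments_to_reads(
    midpoints: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    chrom: str,
    genome_len: int,
) -> List[AlignedRead]:
    reads: List[AlignedRead] = []
    half = cfg.fragment_length // 2
    for mid in midpoints:
        mid = int(round(float(mid)))
        frag_start = max(1, mid - half)
        frag_end = min(genome_len, frag_start + cfg.fragment_length - 1)
        frag_start = max(1, frag_end - cfg.fragment_length + 1)
        # one single-end read per fragment, sequenced from a random end:
        # forward reads run in from the left end, reverse from the right
        if rng.random() < 0.5:
            strand = Strand.FORWARD
            start = frag_start
            end = min(genome_len, start + cfg.read_length - 1)
        else:
            strand = Strand.REVERSE
            end = frag_end
            start = max(1, end - cfg.read_length + 1)
        reads.append(AlignedRead(GenomicInterval(chrom, start, end), strand))
    return reads


def simulate_chip_reads(
    genome: str,
    sites: Sequence[PlantedSite],
    cfg: SimulationConfig,
    seed=None,
    *,
    chrom: str = DEFAULT_CHROM,
) -> List[AlignedRead]:
    """Simulate the immunoprecipitated sample.

    Per site, Poisson(``enrichment``) fragments whose midpoints scatter
    normally (sd = fragment_length / 4) around the site centre, plus uniform
    Poisson background at ``background_depth`` fragments per bp.
    """
    rng = _as_rng(cfg.seed if seed is None else seed)
    genome_len = len(genome)
    reads: List[AlignedRead] = []
    sd = cfg.fragment_length / 4.0
    for site in sites:
        n = rng.poisson(cfg.enrichment)
        mids = rng.normal(site.interval.midpoint, sd, size=n)
        reads.extend(_fragments_to_reads(mids, cfg, rng, chrom, genome_len))
    n_bg = rng.poisson(cfg.background_depth * genome_len)
    bg_mids = rng.uniform(1, genome_len + 1, size=n_bg)
    reads.extend(_fragments_to_reads(bg_mids, cfg, rng, chrom, genome_len))
    return reads


def simulate_input_reads(
    genome: str,
    cfg: SimulationConfig,
    seed=None,
    *,
    chrom: str = DEFAULT_CHROM,
) -> List[AlignedRead]:
    """Simulate the input (non-immunoprecipitated) control: background only."""
    rng = _as_rng(cfg.seed if seed is None else seed)
    genome_len = len(genome)
    n_bg = rng.poisson(cfg.background_depth * genome_len)
    mids = rng.uniform(1, genome_len + 1, size=n_bg)
    return _fragments_to_reads(mids, cfg, rng, chrom, genome_len)


# ---------------------------------------------------------------------------
# Gene -> functional category table (plumbing for the enrichment stage)

DEFAULT_CATEGORY_LABELS = (
    "cell_wall",
    "transport",
    "signalling",
    "metabolism",
    "stress",
    "unknown",
)


def generate_category_table(
    genes: Sequence[GeneModel],
    seed=0,
    labels: Sequence[str] = DEFAULT_CATEGORY_LABELS,
    genome_size: Optional[int] = None,
) -> Tuple[Dict[str, List[str]], int]:
    """Assign 1–2 functional labels per gene, deterministically under seed.

    Returns ``(mapping, genome_size)`` suitable for the enrichment stage.
    """
    rng = _as_rng(seed)
    mapping: Dict[str, List[str]] = {}
    for gene in genes:
        k = 1 + int(rng.random() < 0.3)
        chosen = rng.choice(len(labels), size=k, replace=False)
        mapping[gene.gene_id] = sorted(labels[int(c)] for c in chosen)
    return mapping, (genome_size if genome_size is not None else len(genes))


# ---------------------------------------------------------------------------
# Dataset bundle

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    sites: List[PlantedSite]
    chip_reads: List[AlignedRead]
    input_reads: List[AlignedRead]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


def simulate_dataset(
    cfg: SimulationConfig,
    *,
    chrom: str = DEFAULT_CHROM,
    placement: str = "uniform",
) -> SimulatedDataset:
    """Run the full generator: genome, genes, planted sites, both read sets.

    Stage seeds are spawned from ``cfg.seed`` via ``SeedSequence`` in a fixed
    order, so each stage is independently reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_genome, s_genes, s_sites, s_chip, s_input = [
        np.random.default_rng(child) for child in ss.spawn(5)
    ]
    composition = CompositionModel(cfg.gc_fraction)
    genome = generate_genome(cfg.genome_length, composition, s_genome)
    genes = generate_gene_models(
        cfg.genome_length,
        cfg.n_genes,
        cfg.gene_length_range,
        s_genes,
        chrom=chrom,
    )
    genome, sites = plant_sites(
        genome, genes, cfg.pattern, dict(cfg.site_plan), s_sites,
        chrom=chrom, placement=placement,
    )
    chip = simulate_chip_reads(genome, sites, cfg, s_chip, chrom=chrom)
    inp = simulate_input_reads(genome, cfg, s_input, chrom=chrom)
    return SimulatedDataset(cfg, {chrom: genome}, genes, sites, chip, inp)


def write_dataset(dataset: SimulatedDataset, outdir: str) -> Dict[str, str]:
    """Write FASTA / GFF3 / BED6 outputs plus a JSON truth manifest;
    returns {label: path}."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "chip_reads": os.path.join(outdir, "chip_reads.bed"),
        "input_reads": os.path.join(outdir, "input_reads.bed"),
        "sites": os.path.join(outdir, "planted_sites.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    core_io.write_fasta(dataset.genome, paths["genome"])
    core_io.write_annotation(dataset.genes, paths["genes"])
    core_io.write_reads_bed(dataset.chip_reads, paths["chip_reads"], "chip")
    core_io.write_reads_bed(dataset.input_reads, paths["input_reads"], "input")
    with open(paths["sites"], "w") as handle:
        ordered = sorted(dataset.sites, key=lambda s: (s.interval.chrom, s.interval.start))
        for i, site in enumerate(ordered, start=1):
            iv = site.interval
            handle.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tsite{i}_{site.zone_label}\t0\t"
                f"{site.strand.value}\n"
            )
    truth = {
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else (list(v) if isinstance(v, tuple) else v))
            for k, v in dataset.config.__dict__.items()
        },
        "sites": [
            {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "zone": s.zone_label,
                "gene_id": s.gene_id,
                "strand": s.strand.value,
            }
            for s in dataset.sites
        ],
        "n_chip_reads": len(dataset.chip_reads),
        "n_input_reads": len(dataset.input_reads),
    }
    with open(paths["truth"], "w") as handle:
        json.dump(truth, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths
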