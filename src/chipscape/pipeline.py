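"""End-to-end orchestration: simulate → extend → coverage → call → annotate
→ metagene → motif → enrich, as one seeded, reproducible run.

All randomness flows from one root seed: stage seeds are drawn from
``numpy.random.SeedSequence(seed)`` children in a fixed, documented order
(simulation first, category table second), so re-running any stage on
unchanged inputs is bit-reproducible.  Every emitted file is recorded in a
manifest with its SHA-256 checksum; the manifest carries no timestamps, so
two runs with the same config are byte-identical end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import yaml

from . import __version__
from .category_enrichment import CategoryTable, EnrichmentRow, enrich_categories, write_enrichment_tsv
from .composition import CompositionModel, measure_gc_fraction
from .core import io as core_io
from .core.intervals import Peak
from .metagene import MetageneProfile, compute_zone_profile, write_profile_tsv
from .motif_stats import MotifStats, motif_report
from .peak_annotation import (
    ZONES,
    DistributionSummary,
    annotate_peaks,
    genic_region,
    summarize_distribution,
    write_annotations_tsv,
)
from .read_processing import (
    CallerParams,
    call_enriched_regions,
    extend_reads,
    window_coverage,
)
from .synthetic_data import (
    SimulationConfig,
    generate_category_table,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

import numpy as np


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: simulation settings plus stage parameters.

    Stage defaults are the analysis defaults used throughout the package:
    150-bp windows, 400-nt extension, 3 kb upstream / 1 kb downstream genic
    flanks, 100 metagene segments, the WRGCCCA consensus, and GC content
    measured from the genome ("auto").
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window_size: int = 150
    extend_to: int = 400
    upstream: int = 3_000
    downstream: int = 1_000
    n_segments: int = 100
    pattern: str = "WRGCCCA"
    gc: object = "auto"  # "auto" or a float
    strands: str = "both"
    caller: CallerParams = field(default_factory=CallerParams)
    seed: int = 0
    outdir: str = "chipscape_run"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        caller = CallerParams(**raw.pop("caller", {}))
        return cls(simulation=sim, caller=caller, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["site_plan"] = dict(d["simulation"]["site_plan"])
        d["simulation"]["gene_length_range"] = list(
            d["simulation"]["gene_length_range"]
        )
        # the output location is not part of the analysis; leaving it out
        # keeps two runs of the same config byte-identical
        d.pop("outdir")
        return d


@dataclass
class RunReport:
    """In-memory results of one run plus the paths of everything written."""

    config: RunConfig
    n_chip_reads: int
    n_input_reads: int
    peaks: List[Peak]
    summary: Optional[DistributionSummary]
    profiles: Dict[str, Optional[MetageneProfile]]
    motif: Optional[MotifStats]
    enrichment: List[EnrichmentRow]
    paths: Dict[str, str]

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "seed": self.config.seed,
            "n_chip_reads": self.n_chip_reads,
            "n_input_reads": self.n_input_reads,
            "n_peaks": len(self.peaks),
            "distribution": self.summary.to_dict() if self.summary else None,
            "metagene": {
                zone: (
                    {
                        "n_genes": prof.n_genes,
                        "values": [round(float(v), 6) for v in prof.values],
                    }
                    if prof is not None
                    else None
                )
                for zone, prof in self.profiles.items()
            },
            "motif": self.motif.to_dict() if self.motif else None,
            "enrichment": [
                {
                    "category": r.category,
                    "k": r.k,
                    "n": r.n,
                    "K": r.K,
                    "N": r.N,
                    "pct_sample": round(r.pct_sample, 2),
                    "pct_genome": round(r.pct_genome, 2),
                    "fold": round(r.fold, 1),
                    "p_value": r.p_value,
                }
                for r in self.enrichment
            ],
        }


def _stage_seeds(root_seed: int, n: int) -> List[int]:
    """Deterministic per-stage integer seeds (each < 2**31) derived from the
    root seed; order: simulation, category table, (spare...)."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage on a simulated dataset and write all outputs,
    a consolidated ``report.json`` and a checksum ``manifest.json``."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    sim_seed, cat_seed = _stage_seeds(config.seed, 2)
    sim_cfg = dataclasses.replace(config.simulation, seed=sim_seed)

    logger.info("stage simulate: genome %d bp, %d genes, %d planted sites",
                sim_cfg.genome_length, sim_cfg.n_genes,
                sum(sim_cfg.site_plan.values()))
    dataset = simulate_dataset(sim_cfg)
    paths = write_dataset(dataset, outdir)
    chrom_lengths = dataset.chrom_lengths
    chrom = next(iter(chrom_lengths))
    genome_seq = dataset.genome[chrom]

    logger.info("stage extend: %d treatment / %d input reads -> %d nt",
                len(dataset.chip_reads), len(dataset.input_reads), config.extend_to)
    ext_chip = extend_reads(dataset.chip_reads, config.extend_to, chrom_lengths)
    ext_input = extend_reads(dataset.input_reads, config.extend_to, chrom_lengths)

    logger.info("stage coverage: %d-bp windows", config.window_size)
    cov_chip = window_coverage(ext_chip, chrom_lengths, config.window_size)
    cov_input = window_coverage(ext_input, chrom_lengths, config.window_size)

    logger.info("stage call: Poisson window caller")
    peaks: List[Peak] = []
    for name in sorted(chrom_lengths):
        peaks.extend(
            call_enriched_regions(
                cov_chip[name], cov_input[name], config.caller, chrom_lengths[name]
            )
        )
    paths["peaks_bed"] = os.path.join(outdir, "peaks.bed")
    paths["peaks_tsv"] = os.path.join(outdir, "peaks.tsv")
    core_io.write_peaks(peaks, paths["peaks_bed"], paths["peaks_tsv"])
    logger.info("stage call: %d peaks", len(peaks))

    regions = [
        genic_region(g, chrom_lengths, config.upstream, config.downstream)
        for g in dataset.genes
    ]
    summary = None
    annotations = []
    if peaks:
        annotations = annotate_peaks(
            peaks, dataset.genes, chrom_lengths, config.upstream, config.downstream
        )
        summary = summarize_distribution(annotations)
        paths["annotations"] = os.path.join(outdir, "annotations.tsv")
        write_annotations_tsv(
            annotations, {r.gene_id: r for r in regions}, paths["annotations"]
        )

    profiles: Dict[str, Optional[MetageneProfile]] = {}
    for zone in ZONES:
        profile = compute_zone_profile(regions, ext_chip, zone, config.n_segments)
        profiles[zone] = profile
        if profile is not None:
            paths[f"metagene_{zone}"] = os.path.join(outdir, f"metagene_{zone}.tsv")
            write_profile_tsv(profile, paths[f"metagene_{zone}"])

    motif = None
    if peaks:
        gc = (
            measure_gc_fraction(genome_seq)
            if config.gc == "auto"
            else float(config.gc)
        )
        peak_seqs = [
            genome_seq[p.interval.start - 1 : p.interval.end]
            for p in peaks
            if p.interval.chrom == chrom
        ]
        motif = motif_report(
            peak_seqs, config.pattern, CompositionModel(gc), config.strands
        )
        paths["motif"] = os.path.join(outdir, "motif_stats.json")
        with open(paths["motif"], "w") as handle:
            json.dump(motif.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    enrichment: List[EnrichmentRow] = []
    target_genes = sorted({a.gene_id for a in annotations if a.gene_id is not None})
    if target_genes:
        mapping, genome_size = generate_category_table(dataset.genes, cat_seed)
        enrichment = enrich_categories(
            target_genes, CategoryTable(mapping, genome_size), compute_qvalues=True
        )
        paths["enrichment"] = os.path.join(outdir, "enrichment.tsv")
        write_enrichment_tsv(enrichment, paths["enrichment"])

    report = RunReport(
        config=config,
        n_chip_reads=len(dataset.chip_reads),
        n_input_reads=len(dataset.input_reads),
        peaks=peaks,
        summary=summary,
        profiles=profiles,
        motif=motif,
        enrichment=enrichment,
        paths=paths,
    )

    paths["config"] = os.path.join(outdir, "config.yaml")
    with open(paths["config"], "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
    paths["report"] = os.path.join(outdir, "report.json")
    with open(paths["report"], "w") as handle:
        json.dump(report.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"simulation": sim_seed, "category_table": cat_seed},
        "files": {
            label: {"path": os.path.basename(p), "sha256": _sha256(p)}
            for label, p in sorted(paths.items())
            if label != "manifest"
        },
    }
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    with open(paths["manifest"], "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report
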