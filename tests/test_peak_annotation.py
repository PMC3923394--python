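"""Genic-region geometry, anchor-point classification (vs a brute-force
oracle) and distribution summaries."""

from __future__ import annotations

import numpy as np
import pytest

from chipscape.core.intervals import GeneModel, GenomicInterval, Peak, Strand
from chipscape.peak_annotation import (
    classify_peak,
    genic_region,
    summarize_distribution,
    PeakAnnotation,
)

CHROM_LENGTHS = {"chr1": 1_000_000}


def _gene(gene_id, start, end, strand=Strand.FORWARD):
    return GeneModel(gene_id, GenomicInterval("chr1", start, end), strand)


class TestGenicRegion:
    def test_forward_gene_partition(self):
        region = genic_region(_gene("g", 10_000, 12_000), CHROM_LENGTHS)
        assert region.promoter == GenomicInterval("chr1", 7_000, 9_999)
        assert region.body == GenomicInterval("chr1", 10_000, 12_000)
        assert region.downstream == GenomicInterval("chr1", 12_001, 13_000)

    def test_reverse_gene_mirrors(self):
        region = genic_region(_gene("g", 10_000, 12_000, Strand.REVERSE), CHROM_LENGTHS)
        assert region.promoter == GenomicInterval("chr1", 12_001, 15_000)
        assert region.downstream == GenomicInterval("chr1", 9_000, 9_999)
        assert region.tss == 12_000

    def test_promoter_clamped_at_chromosome_start(self):
        region = genic_region(_gene("g", 2_000, 4_000), CHROM_LENGTHS)
        assert region.promoter == GenomicInterval("chr1", 1, 1_999)

    def test_zones_partition_the_genic_region(self):
        """Promoter/body/downstream abut with no gaps or overlaps and cover
        gene length + 4,000 bp when unclamped."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            start = int(rng.integers(5_000, 900_000))
            length = int(rng.integers(200, 8_000))
            strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            region = genic_region(_gene("g", start, start + length - 1, strand),
                                  CHROM_LENGTHS)
            zones = [region.promoter, region.body, region.downstream]
            assert sum(z.length for z in zones) == length + 4_000
            ordered = sorted(zones, key=lambda z: z.start)
            assert ordered[0].end + 1 == ordered[1].start
            assert ordered[1].end + 1 == ordered[2].start
            for pos in (region.span.start, region.span.end):
                assert region.zone_of("chr1", pos) is not None


class TestClassifyPeak:
    @pytest.fixture()
    def regions(self):
        return [genic_region(_gene("g1", 10_000, 12_000), CHROM_LENGTHS)]

    @pytest.mark.parametrize(
        "anchor,zone", [(8_000, "promoter"), (11_000, "gene_body"),
                        (12_500, "downstream"), (6_900, "intergenic")]
    )
    def test_anchor_classification(self, regions, anchor, zone):
        peak = Peak(GenomicInterval("chr1", anchor - 50, anchor + 50), 1.0, summit=anchor)
        ann = classify_peak(peak, regions)
        assert ann.zone == zone
        assert (ann.gene_id is None) == (zone == "intergenic")

    def test_midpoint_used_when_no_summit(self, regions):
        peak = Peak(GenomicInterval("chr1", 10_900, 11_100), 1.0)
        assert classify_peak(peak, regions).anchor == 11_000

    def test_nearest_tss_wins_between_neighboring_genes(self):
        # downstream gene g2's promoter reaches back over g1's 3' flank
        genes = [
            _gene("g1", 10_000, 12_000),
            _gene("g2", 13_500, 15_000),
        ]
        regions = [genic_region(g, CHROM_LENGTHS) for g in genes]
        # anchor 12,900: in g1's downstream zone (2,900 bp from its TSS) and
        # in g2's promoter (600 bp from its TSS at 13,500) -> g2 wins
        ann = classify_peak(Peak(GenomicInterval("chr1", 12_850, 12_950), 1.0), regions)
        assert ann.gene_id == "g2" and ann.zone == "promoter"

    def test_exact_tie_breaks_lexicographically(self):
        genes = [
            _gene("gA", 10_000, 12_000),
            _gene("gB", 8_000, 9_000, Strand.REVERSE),
        ]
        regions = [genic_region(g, CHROM_LENGTHS) for g in genes]
        # anchor 9,500: 500 bp from both TSSs (10,000 fwd; 9,000 rev)
        ann = classify_peak(Peak(GenomicInterval("chr1", 9_450, 9_550), 1.0), regions)
        assert ann.gene_id == "gA"

    def test_agrees_with_brute_force_oracle(self):
        """Random genes and anchors: classification equals an exhaustive
        membership test over every zone of every gene."""
        rng = np.random.default_rng(4)
        genes = []
        cursor = 20_000
        for i in range(8):
            length = int(rng.integers(500, 3_000))
            strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            genes.append(_gene(f"g{i}", cursor, cursor + length - 1, strand))
            cursor += length + int(rng.integers(500, 6_000))
        regions = [genic_region(g, CHROM_LENGTHS) for g in genes]
        for anchor in rng.integers(1, cursor + 10_000, size=300):
            anchor = int(anchor)
            peak = Peak(GenomicInterval("chr1", anchor, anchor), 1.0)
            ann = classify_peak(peak, regions)
            hits = []
            for gene, region in zip(genes, regions):
                zone = region.zone_of("chr1", anchor)
                if zone is not None:
                    hits.append((abs(anchor - gene.tss), gene.gene_id, zone))
            if not hits:
                assert ann.zone == "intergenic"
            else:
                dist, gene_id, zone = min(hits)
                assert (ann.gene_id, ann.zone) == (gene_id, zone)


class TestSummarizeDistribution:
    def _ann(self, zone, gene_id):
        return PeakAnnotation(
            Peak(GenomicInterval("chr1", 100, 200), 1.0), zone, gene_id, 150
        )

    def test_constructed_mix(self):
        anns = (
            [self._ann("promoter", "g1")] * 3
            + [self._ann("gene_body", "g2")] * 3
            + [self._ann("downstream", "g3")]
            + [self._ann("intergenic", None)] * 3
        )
        summary = summarize_distribution(anns)
        assert summary.n_peaks == 10 and summary.n_genic == 7
        assert summary.fraction_genic == pytest.approx(0.70)
        assert summary.zone_fractions["promoter"] == pytest.approx(3 / 7)
        assert summary.zone_fractions["downstream"] == pytest.approx(1 / 7)
        assert summary.zone_percent("promoter") == 43
        assert sum(summary.zone_fractions.values()) == pytest.approx(1.0)

    def test_all_intergenic_reports_absent_zone_split(self):
        summary = summarize_distribution([self._ann("intergenic", None)] * 4)
        assert summary.fraction_genic == 0.0
        assert summary.zone_fractions is None
        assert summary.zone_percent("promoter") is None

    def test_single_promoter_peak(self):
        summary = summarize_distribution([self._ann("promoter", "g1")])
        assert summary.zone_percent("promoter") == 100
        assert summary.zone_percent("gene_body") == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([])

    def test_inconsistent_annotation_rejected(self):
        with pytest.raises(ValueError):
            self._ann("promoter", None)
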