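"""Genomic coordinate primitives.

All coordinates are 1-based and fully closed: an interval ``[start, end]``
contains both endpoints and has length ``end - start + 1``.  This is the
convention of GFF3 and SAM; BED's 0-based half-open coordinates are converted
at the I/O boundary (see :mod:`chipscape.core.io`) and never appear inside the
package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Strand(enum.Enum):
    """Orientation of a stranded feature on the reference."""

    FORWARD = "+"
    REVERSE = "-"

    def opposite(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD

    @classmethod
    def from_symbol(cls, symbol: str) -> "Strand":
        if symbol == "+":
            return cls.FORWARD
        if symbol == "-":
            return cls.REVERSE
        raise ValueError(f"unknown strand symbol {symbol!r} (expected '+' or '-')")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on one chromosome.

    Invariants (enforced at construction): ``start >= 1`` and
    ``end >= start``.  Length is ``end - start + 1``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        """Floor midpoint; for even lengths the tie breaks toward ``start``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two closed intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains_position(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def clamped(self, chrom_length: int) -> "GenomicInterval":
        """Intersect with ``[1, chrom_length]``; the result must be nonempty."""
        return GenomicInterval(
            self.chrom, max(1, self.start), min(chrom_length, self.end)
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length of a closed interval, ``end - start + 1``."""
    return iv.length


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


def interval_midpoint(iv: GenomicInterval) -> int:
    return iv.midpoint


@dataclass(frozen=True)
class AlignedRead:
    """A mapped sequencing read reduced to its aligned span and strand."""

    interval: GenomicInterval
    strand: Strand


@dataclass(frozen=True)
class Peak:
    """A scored enriched interval; ``summit`` is the position of maximal
    signal when known."""

    interval: GenomicInterval
    score: float
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be non-negative, got {self.score}")
        if self.summit is not None and not (
            self.interval.start <= self.summit <= self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside peak interval "
                f"[{self.interval.start}, {self.interval.end}]"
            )

    @property
    def anchor(self) -> int:
        """Position used to localise the peak: summit if known, else midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene spanning TSS to TES, with optional exon structure.

    ``interval`` is the genomic span irrespective of strand; the TSS is the
    5' end in transcription orientation (``interval.start`` for forward
    genes, ``interval.end`` for reverse genes) and the TES is the opposite
    end.  Exons are stored in genome coordinate order, non-overlapping and
    nested within the gene span.
    """

    gene_id: str
    interval: GenomicInterval
    strand: Strand
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for exon in exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError(f"exon chromosome {exon.chrom} != gene {self.interval.chrom}")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"exon {exon} outside gene span {self.interval}")
            if prev_end is not None and exon.start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand is Strand.FORWARD else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand is Strand.FORWARD else self.interval.start


def sort_key(iv: GenomicInterval):
    """Deterministic (chrom, start, end) ordering used by every writer."""
    return (iv.chrom, iv.start, iv.end)
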