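"""Read-level computations: fragment-length extension, fixed-window
coverage, and a simple treatment-vs-input enrichment caller.

Single-end ChIP reads tag only one end of each ~400 bp chromatin fragment,
so each ~51 nt read is extended, strand-aware, to the expected fragment
length before any coverage is computed.  Coverage is counted in consecutive
150-bp windows (window k covers positions ``[(k-1)*w+1, k*w]``); a read
increments every window it overlaps.  Enrichment is then called per window
with an upper-tail Poisson test of the treatment count against the
library-size-scaled input count, and runs of significant windows merge into
peaks.  The caller is deliberately simple plumbing — a local Poisson test
with no model building, read shifting or FDR sweep — because everything this
package contributes sits downstream of peak calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .core.intervals import AlignedRead, GenomicInterval, Peak, Strand

DEFAULT_WINDOW = 150
DEFAULT_TARGET_LENGTH = 400


def extend_reads(
    reads: Sequence[AlignedRead],
    target_length: int = DEFAULT_TARGET_LENGTH,
    chrom_lengths: Dict[str, int] | None = None,
) -> List[GenomicInterval]:
    """Extend each read, strand-aware, to the expected fragment length.

    Forward reads keep their start and grow rightward; reverse reads keep
    their end and grow leftward.  Results are clamped to ``[1,
    chrom_length]``.  Reads already at least ``target_length`` long pass
    through unchanged.
    """
    if target_length < 1:
        raise ValueError(f"target_length must be >= 1, got {target_length}")
    chrom_lengths = chrom_lengths or {}
    out: List[GenomicInterval] = []
    for read in reads:
        iv = read.interval
        if iv.chrom not in chrom_lengths:
            raise KeyError(f"unknown chromosome {iv.chrom!r} in chrom_lengths")
        limit = chrom_lengths[iv.chrom]
        if iv.length >= target_length:
            out.append(iv)
            continue
        if read.strand is Strand.FORWARD:
            start, end = iv.start, iv.start + target_length - 1
        else:
            start, end = iv.end - target_length + 1, iv.end
        out.append(GenomicInterval(iv.chrom, max(1, start), min(limit, end)))
    return out


@dataclass
class WindowCoverage:
    """Per-chromosome vector of read counts in consecutive fixed windows."""

    chrom: str
    window_size: int
    counts: np.ndarray  # int64, one entry per window from position 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("window counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def window_interval(self, k: int, chrom_length: Optional[int] = None) -> GenomicInterval:
        """1-based window index -> genomic interval (clamped when the
        chromosome length is given)."""
        if not 1 <= k <= self.n_windows:
            raise IndexError(f"window {k} out of range 1..{self.n_windows}")
        start = (k - 1) * self.window_size + 1
        end = k * self.window_size
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end)


def window_coverage(
    intervals: Iterable[GenomicInterval],
    chrom_lengths: Dict[str, int],
    window_size: int = DEFAULT_WINDOW,
) -> Dict[str, WindowCoverage]:
    """Count, per chromosome, how many intervals overlap each window.

    An interval spanning a window boundary increments every window it
    touches, so window totals are overlap counts, not a partition of reads.
    """
    grids: Dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_windows = -(-length // window_size)  # ceil
        grids[chrom] = np.zeros(n_windows + 1, dtype=np.int64)  # +1 for diff trick
    for iv in intervals:
        if iv.chrom not in grids:
            raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")
        first = (iv.start - 1) // window_size
        last = (iv.end - 1) // window_size
        last = min(last, len(grids[iv.chrom]) - 2)
        grids[iv.chrom][first] += 1
        grids[iv.chrom][last + 1] -= 1
    return {
        chrom: WindowCoverage(chrom, window_size, np.cumsum(diff[:-1]))
        for chrom, diff in grids.items()
    }


@dataclass(frozen=True)
class CallerParams:
    """Settings of the Poisson window caller.

    ``scale`` multiplies the input count to put both libraries on the same
    depth; ``None`` means derive it as (total treatment reads)/(total input
    reads) over the grid.  ``pseudocount`` regularises empty input windows.
    """

    p_threshold: float = 1e-5
    min_windows: int = 2
    pseudocount: float = 1.0
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_windows < 1:
            raise ValueError("min_windows must be >= 1")


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def call_enriched_regions(
    chip: WindowCoverage,
    control: WindowCoverage,
    params: CallerParams = CallerParams(),
    chrom_length: Optional[int] = None,
) -> List[Peak]:
    """Call windows enriched in the treatment over the scaled input and merge
    adjacent significant windows into peaks.

    A window is significant when the upper-tail Poisson p-value of its
    treatment count, with mean ``scale * (input count + pseudocount)``, falls
    below ``p_threshold``.  Runs of at least ``min_windows`` consecutive
    significant windows become one peak whose score is -10*log10 of the best
    window p-value (truncated to one decimal) and whose summit is the
    midpoint of the run's highest-count window.
    """
    if chip.chrom != control.chrom or chip.window_size != control.window_size \
            or chip.n_windows != control.n_windows:
        raise ValueError("treatment and input coverage are on different grids")
    scale = params.scale
    if scale is None:
        chip_total = int(chip.counts.sum())
        control_total = int(control.counts.sum())
        scale = chip_total / control_total if control_total > 0 else 1.0
    lam = scale * (control.counts.astype(float) + params.pseudocount)
    with np.errstate(divide="ignore"):
        logsf = stats.poisson.logsf(chip.counts - 1, lam)  # log P(X >= k)
    logsf = np.where(chip.counts <= 0, 0.0, logsf)
    pvals = np.exp(logsf)
    significant = pvals < params.p_threshold

    peaks: List[Peak] = []
    n = chip.n_windows
    i = 0
    while i < n:
        if not significant[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and significant[j + 1]:
            j += 1
        if j - i + 1 >= params.min_windows:
            start_iv = chip.window_interval(i + 1, chrom_length)
            end_iv = chip.window_interval(j + 1, chrom_length)
            run = slice(i, j + 1)
            # score from log-space tail, robust to p underflowing to 0
            best_logp = float(np.min(logsf[run]))
            score = -10.0 * best_logp / math.log(10)
            score = math.floor(score * 10) / 10  # truncate to 1 decimal
            top = i + int(np.argmax(chip.counts[run]))
            summit = chip.window_interval(top + 1, chrom_length).midpoint
            peaks.append(
                Peak(
                    GenomicInterval(chip.chrom, start_iv.start, end_iv.end),
                    score=score,
                    summit=summit,
                )
            )
        i = j + 1
    return peaks
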