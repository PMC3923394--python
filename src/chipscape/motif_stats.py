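"""Degenerate consensus-motif statistics against a base-composition null.

The consensus of interest is the binding motif (A/T)(A/G)GCCCA, written in
IUPAC degenerate code as ``WRGCCCA``.  Sequences (typically peak sequences)
are scanned for all — including overlapping — occurrences on one or both
strands; the observed per-bp hit frequency is compared with the frequency
expected by chance under a zero-order composition model (independent bases at
a given GC content), and the ratio of the two is reported as the fold
difference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .composition import CompositionModel

IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_PATTERN = "WRGCCCA"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompiledPattern:
    """A degenerate pattern expanded into per-position allowed-base sets,
    with a pre-built overlapping-occurrence scanner for each strand."""

    iupac: str
    position_sets: Tuple[str, ...]
    rc_position_sets: Tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.iupac)

    @property
    def rc_iupac(self) -> str:
        return reverse_complement(self.iupac)

    def _regex(self, sets: Tuple[str, ...]) -> "re.Pattern[str]":
        # lookahead makes overlapping occurrences countable; N in the
        # scanned sequence matches nothing because classes list ACGT only
        return re.compile("(?=" + "".join(f"[{s}]" for s in sets) + ")")

    def matches_at(self, seq: str, offset: int, reverse: bool = False) -> bool:
        sets = self.rc_position_sets if reverse else self.position_sets
        if offset + len(sets) > len(seq):
            return False
        return all(seq[offset + i] in sets[i] for i in range(len(sets)))

    def count_in(self, seq: str, reverse: bool = False) -> int:
        sets = self.rc_position_sets if reverse else self.position_sets
        return len(self._regex(sets).findall(seq))


def compile_pattern(iupac: str) -> CompiledPattern:
    """Expand an IUPAC string into a matcher (plus its reverse-complement
    matcher); raises on any non-IUPAC character, naming its position."""
    if not iupac:
        raise ValueError("empty pattern")
    sets: List[str] = []
    for pos, char in enumerate(iupac.upper(), start=1):
        try:
            sets.append(IUPAC_CODES[char])
        except KeyError:
            raise ValueError(
                f"illegal IUPAC character {char!r} at position {pos}"
            ) from None
    rc = reverse_complement(iupac.upper())
    rc_sets = [IUPAC_CODES[c] for c in rc]
    return CompiledPattern(iupac.upper(), tuple(sets), tuple(rc_sets))


@dataclass(frozen=True)
class MotifStats:
    """Observed vs expected per-bp motif frequency and their ratio."""

    n_hits: int
    total_bp: int
    observed_freq: float
    expected_freq: float
    fold: float
    strands_scanned: str  # "forward_only" | "both"

    def to_dict(self) -> dict:
        return {
            "n_hits": self.n_hits,
            "total_bp": self.total_bp,
            "observed_freq": self.observed_freq,
            "expected_freq": self.expected_freq,
            "fold": self.fold,
            "strands_scanned": self.strands_scanned,
        }


def count_hits(
    sequences: Iterable[str],
    pattern: CompiledPattern | str,
    strands: str = "both",
) -> Tuple[int, int]:
    """Count all (overlapping) pattern occurrences over the sequences.

    In both-strand mode the reverse-complement pattern is additionally
    matched at every offset of the forward text.  ``N`` bases match nothing
    but still contribute to ``total_bp``.
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    _check_strands(strands)
    n_hits = 0
    total_bp = 0
    for seq in sequences:
        seq = seq.upper()
        total_bp += len(seq)
        n_hits += pattern.count_in(seq)
        if strands == "both":
            n_hits += pattern.count_in(seq, reverse=True)
    return n_hits, total_bp


def expected_frequency(
    pattern: CompiledPattern | str,
    composition: CompositionModel,
    strands: str = "both",
) -> float:
    """Per-bp chance probability of a motif occurrence under the zero-order
    composition null: the product over positions of the summed probabilities
    of the allowed bases, plus (in both-strand mode) the same product for the
    reverse-complement pattern."""
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    _check_strands(strands)
    probs = composition.base_probabilities
    forward = 1.0
    for allowed in pattern.position_sets:
        forward *= sum(probs[b] for b in allowed)
    if strands == "forward_only":
        return forward
    reverse = 1.0
    for allowed in pattern.rc_position_sets:
        reverse *= sum(probs[b] for b in allowed)
    return forward + reverse


def motif_report(
    sequences: Sequence[str],
    pattern: CompiledPattern | str,
    composition: CompositionModel,
    strands: str = "both",
) -> MotifStats:
    """Assemble observed frequency, chance expectation and their fold ratio
    for a set of (peak) sequences."""
    if not sequences:
        raise ValueError("motif_report requires at least one sequence")
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    n_hits, total_bp = count_hits(sequences, pattern, strands)
    observed = n_hits / total_bp if total_bp else 0.0
    expected = expected_frequency(pattern, composition, strands)
    if expected > 0:
        fold = observed / expected
    else:
        fold = float("nan")
    return MotifStats(n_hits, total_bp, observed, expected, fold, strands)


def _check_strands(strands: str) -> None:
    if strands not in ("both", "forward_only"):
        raise ValueError(
            f"strands must be 'both' or 'forward_only', got {strands!r}"
        )
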