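"""Zero-order base-composition model shared by the generator and the motif
null: independent bases with p(G) = p(C) = gc/2 and p(A) = p(T) = (1-gc)/2."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict


@dataclass(frozen=True)
class CompositionModel:
    """Base composition parameterised by GC fraction (strictly inside (0, 1));
    the default 0.332 is the tomato genome's GC content."""

    gc_fraction: float = 0.332

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError(
                f"gc_fraction must lie strictly in (0, 1), got {self.gc_fraction}"
            )

    @property
    def base_probabilities(self) -> Dict[str, float]:
        gc = self.gc_fraction
        return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


def measure_gc_fraction(sequence: str) -> float:
    """Observed (G+C)/length of a sequence (case-insensitive)."""
    if not sequence:
        raise ValueError("cannot measure GC content of an empty sequence")
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)
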