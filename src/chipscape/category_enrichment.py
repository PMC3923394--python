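"""Functional-category over-representation of target genes.

Given the set of genes a factor binds (the target set) and a gene→category
table over the annotated genome, each category is summarised by the percent
of the target set it covers, its percent in the whole genome, the fold
over-representation (the ratio of the two percentages), and a one-sided
hypergeometric (Fisher) p-value for observing at least the target-set count
by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
import logging
import math

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryTable:
    """Gene→categories mapping over an annotated universe of
    ``genome_size`` genes (the mapping may cover only a subset)."""

    mapping: Mapping[str, Sequence[str]]
    genome_size: int

    def __post_init__(self) -> None:
        if self.genome_size < len(self.mapping):
            raise ValueError(
                "genome_size smaller than the number of mapped genes"
            )
        for gene, labels in self.mapping.items():
            if not labels or any(not lab for lab in labels):
                raise ValueError(f"gene {gene!r} has an empty category label")

    def genome_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for labels in self.mapping.values():
            for label in set(labels):
                counts[label] = counts.get(label, 0) + 1
        return counts

    @classmethod
    def from_tsv(cls, path: str, genome_size: int) -> "CategoryTable":
        """Read a two-column ``gene_id<TAB>category`` table (repeated gene
        rows accumulate categories)."""
        mapping: Dict[str, List[str]] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected gene_id<TAB>category"
                    )
                mapping.setdefault(fields[0], []).append(fields[1])
        return cls(mapping, genome_size)


@dataclass(frozen=True)
class EnrichmentRow:
    """One category's over-representation summary.

    ``pct_sample`` and ``pct_genome`` are percentages; ``fold`` is their
    exact ratio (``(k/n)/(K/N)``), with the 1-decimal rounding applied only
    in reports.
    """

    category: str
    k: int  # category members in the target set
    n: int  # target-set size
    K: int  # category members in the genome
    N: int  # annotated genome size
    p_value: float
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("k must satisfy 0 <= k <= min(n, K)")

    @property
    def pct_sample(self) -> float:
        return 100.0 * self.k / self.n

    @property
    def pct_genome(self) -> float:
        return 100.0 * self.K / self.N

    @property
    def fold(self) -> float:
        return (self.k / self.n) / (self.K / self.N)

    @property
    def printed_fold(self) -> float:
        """Fold as it appears in reports: the ratio of the two percentages
        after their 2-decimal rounding, rounded to 1 decimal."""
        return round(fold_enrichment(round(self.pct_sample, 2),
                                     round(self.pct_genome, 2)), 1)


def fold_enrichment(pct_sample: float, pct_genome: float) -> float:
    """Fold over-representation from the two percentages (exact ratio;
    callers round to one decimal for reports)."""
    if pct_genome <= 0:
        raise ValueError("pct_genome must be positive for a defined fold")
    return pct_sample / pct_genome


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws),
    computed in log space by scipy."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"infeasible counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(pvalues: Sequence[float]) -> List[float]:
    """BH step-up q-values, preserving input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    qvals = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        qvals[idx] = running
    return qvals


def enrich_categories(
    target_genes: Iterable[str],
    table: CategoryTable,
    compute_qvalues: bool = False,
) -> List[EnrichmentRow]:
    """Build one row per category present in the target set, sorted by
    ascending p-value (ties broken by category label).

    Target genes missing from the annotation table are dropped with a
    warning; genes carrying several categories count once per category.
    """
    targets = sorted(set(target_genes))
    if not targets:
        raise ValueError("empty target gene set")
    known = [g for g in targets if g in table.mapping]
    dropped = len(targets) - len(known)
    if dropped:
        logger.warning("%d target gene(s) absent from the category table", dropped)
    if not known:
        raise ValueError("no target gene is present in the category table")
    n = len(known)
    genome_counts = table.genome_counts()
    sample_counts: Dict[str, int] = {}
    for gene in known:
        for label in set(table.mapping[gene]):
            sample_counts[label] = sample_counts.get(label, 0) + 1
    rows = []
    for category in sorted(sample_counts):
        k = sample_counts[category]
        K = genome_counts[category]
        rows.append(
            EnrichmentRow(
                category, k, n, K, table.genome_size,
                hypergeometric_upper_tail(k, n, K, table.genome_size),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.category))
    if compute_qvalues:
        qvals = benjamini_hochberg([r.p_value for r in rows])
        rows = [
            EnrichmentRow(r.category, r.k, r.n, r.K, r.N, r.p_value, q)
            for r, q in zip(rows, qvals)
        ]
    return rows


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str) -> None:
    with open(path, "w") as handle:
        handle.write(
            "category\tcount\tp_value\tpct_sample\tpct_genome\tfold\t"
            "pct_sample_exact\tpct_genome_exact\tfold_exact\tq_value\n"
        )
        for row in rows:
            q = "" if row.q_value is None else f"{row.q_value:.3g}"
            handle.write(
                f"{row.category}\t{row.k}\t{row.p_value:.3g}\t"
                f"{row.pct_sample:.2f}%\t{row.pct_genome:.2f}%\t{row.fold:.1f}\t"
                f"{row.pct_sample!r}\t{row.pct_genome!r}\t{row.fold!r}\t{q}\n"
            )
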