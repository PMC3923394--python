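# Methods

## Coordinate conventions

All internal coordinates are 1-based and fully closed: an interval
`[start, end]` contains both endpoints and has length `end − start + 1`.
This is the GFF3/SAM convention and makes published peak-table lengths
reproduce exactly. BED files (0-based, half-open) are converted at the I/O
boundary and nowhere else. Midpoints of even-length intervals floor toward
`start` — a deterministic, documented tie-break. Chromosome names match by
exact string equality; no "chr" aliasing is attempted, to avoid silent
mis-joins between files from different sources.

From SAM records only the chromosome, 1-based position, aligned span and
the reverse-strand flag are consumed. Mapping-quality and mismatch
filtering are alignment-time concerns and are assumed done upstream.

## Read extension and window coverage

Single-end ChIP libraries sequence ~51 nt from one end of each ~400 bp
sonicated fragment, so coverage computed from raw tags misplaces the
signal by up to half a fragment. `extend_reads` therefore grows each read
to `target_length` (default 400 bp): forward reads keep their start,
reverse reads keep their end, results are clamped to the chromosome, and
reads already at least the target length pass through unchanged.

`window_coverage` counts extended reads in consecutive windows of
`window_size` (default 150 bp; window *k* spans `[(k−1)·w+1, k·w]`). "Falls
within" is implemented as overlap counting: a read spanning a boundary
increments every window it touches. This matches coverage-histogram
semantics (what a genome browser displays) and is what the per-base test
oracle checks.

## The enrichment caller

The caller is intentionally minimal plumbing — the package's contributions
sit downstream of peak calling, and the original study's full caller
settings are not public. Per window, the treatment count `c` is tested
against a Poisson mean `λ = s · (c_input + pseudocount)` where `s` is a
library-size scale (default: total treatment reads / total input reads on
the grid) and the pseudocount (default 1.0) regularises empty input
windows. A window is significant when the upper tail `P(X ≥ c)` falls below
`p_threshold` (default 1e-5); runs of at least `min_windows` (default 2)
adjacent significant windows merge into one peak. Requiring two consecutive
windows suppresses isolated background spikes while a real site — whose
extended-read footprint spans several hundred bp — always lights up
multiple windows. The peak score is `−10·log10` of the best window p-value
(computed from the log survival function, so it survives p-value
underflow), truncated to one decimal; the summit is the midpoint of the
run's highest-count window. The score formula is cosmetic, chosen to
resemble familiar peak-caller scores. There is no model building, read
shifting, duplicate handling or FDR sweep.

## Genic zones and peak annotation

A gene's genic region spans 3 kb upstream of the TSS through 1 kb
downstream of the TES, strand-aware. Within it, promoter (3 kb upstream),
gene body (TSS..TES including introns) and downstream (1 kb) abut exactly;
flanks are clamped at chromosome ends, and a gene flush against a
chromosome end (no room for any flank) is rejected explicitly rather than
silently given an empty zone.

Peaks are classified by a single anchor point — the summit when known,
otherwise the midpoint — rather than by overlap extent, so the four labels
partition the peaks and reported percentages sum to 100. When an anchor
falls inside the genic regions of several genes, the gene with the nearest
TSS wins; exact ties go to the lexicographically smallest gene id
(deterministic and biologically conventional). Summary percentages are
rounded to integers in reports; exact fractions are retained in machine
output.

## Metagene profiles

For each zone, genes are first selected whose coverage is *mainly* in that
zone: a gene qualifies when more than `majority_threshold` (default 0.5) of
its genic-region coverage falls there. Coverage attribution for this
selection counts extended reads overlapping each zone; a read overlapping
two zones counts in both. The threshold is configurable because no
principled value exists; 0.5 is the natural reading of "mainly".

Each selected gene's zone is split into 100 consecutive segments; when the
zone length is not a multiple of 100, the first `L mod 100` segments carry
one extra base, and zones shorter than 100 bp leave trailing segments
empty. A read increments every segment it overlaps. Vectors are reported
5'→3' in gene orientation (reversed for reverse-strand genes), scaled to
the gene's own maximum segment count (per-gene max normalisation removes
depth differences between genes; a global-max alternative would let deeply
covered genes dominate), and averaged element-wise with equal gene weight.
All-zero vectors are skipped with a warning, never propagated as NaN.

## Motif statistics

Degenerate patterns use the IUPAC alphabet; the default consensus
`WRGCCCA` encodes (A/T)(A/G)GCCCA. Scanning counts **all** occurrences,
overlapping ones included, and by default scans both strands (a
transcription factor binds double-stranded DNA; forward-only is available
as a flag). `N` bases in the scanned sequence match nothing but still count
in the scanned-bp denominator — a conservative choice for the observed
frequency.

The null is zero-order: independent bases with `p(G)=p(C)=gc/2`,
`p(A)=p(T)=(1−gc)/2`. The expected per-bp frequency is the product over
pattern positions of the allowed-base probability sums, plus the
reverse-complement pattern's product in both-strand mode. For `WRGCCCA` at
GC 0.332 this gives 8.47×10⁻⁵ (single strand) and 1.69×10⁻⁴ (both
strands). No Markov background is fitted: the null models exactly "expected
by chance at this GC content", nothing more.

## Category over-representation

Fold over-representation of a category is `(k/n)/(K/N)` — target-set
percentage over genome percentage. Reports additionally show the
"printed" fold (the ratio of the percentages after their 2-decimal
rounding), since published tables are typically computed that way.
Significance is the one-sided hypergeometric upper tail, evaluated in log
space; genes carrying several categories count once per category, and
Benjamini–Hochberg q-values are available but off by default. Target genes
missing from the annotation table are dropped with a warning.

## The simulator

`synthetic_data` emulates the statistical structure the analysis assumes:

- **Genome**: i.i.d. bases from the composition model; default GC 0.332
  (the tomato genome's value). Real genomes are not zero-order — no repeat
  structure, isochores or mappability variation are modelled.
- **Genes**: stranded, 1–5 exons, placed so genic regions (gene ± 3 kb/1 kb
  flanks) are pairwise disjoint; an infeasible request raises rather than
  truncates. Default 20 genes of 400–800 bp on 100 kb — genes are
  miniaturised so that a multi-gene genome with full-size flanks fits a
  desk-scale sequence; flank sizes are kept at the analysis defaults
  because the annotation geometry is what is under test.
- **Planted sites**: concrete expansions of the consensus written into
  chosen zones (uniformly placed, or at zone centres for shape tests), on
  a random strand (reverse-strand sites appear as the reverse complement
  on the forward genome string), never overlapping each other. Ground
  truth is returned and written to a JSON manifest.
- **Reads**: per site, Poisson(`enrichment`) fragments with midpoints
  Gaussian around the site centre (sd = fragment_length/4 — a standard
  ChIP fragment-position model producing centred peaks), plus uniform
  Poisson background (`background_depth` fragments/bp). Each fragment
  yields one single-end read of `read_length` from a uniformly chosen end:
  forward from the left end, reverse from the right. Defaults: fragment
  400 bp, read 51 nt, enrichment 50 fragments/site, background 0.01
  fragments/bp. No sequencing errors, quality scores, PCR duplicates or
  mappability artifacts are simulated — passing tests demonstrate the
  analysis logic, not robustness to those real-data pathologies.
- **Category table**: the enrichment stage needs a gene→category input; the
  generator assigns 1–2 labels per gene from a small fixed vocabulary,
  deterministically under its stage seed. It is plumbing for end-to-end
  runs, not a model of any real ontology.

All generator output is byte-identical under a fixed seed. The pipeline
derives per-stage seeds from one root seed via `numpy.random.SeedSequence`
in a fixed order, so stages are independently reproducible and the
manifest (which checksums every emitted file and carries no timestamps) is
byte-identical across repeated runs.

## Test design and problem sizes

Wherever a computation has an independent closed form or brute force, the
tests check against it: motif scanning against an exhaustive
expansion-and-offset scan, window coverage against a per-base oracle, the
Poisson tail against an lgamma series sum, the hypergeometric tail against
exact rational enumeration for every population up to N = 12. Statistical
checks on generator output use 3-standard-deviation bands (binomial for GC
content and motif counts, CLT for fragment centring), sized so a correct
implementation fails with probability ≪ 1%. Suite-level problem sizes —
1 Mb for the composition checks, 200 random 5 kb sequences for scanner
equivalence, the default 100 kb simulation for end-to-end recovery — keep
the whole suite in the seconds range.

The profile-shape checks use a center-planted variant of the default
simulation (10 genes of 3–4 kb, one site at each gene-body midpoint),
because a centred-binding prediction is only defined when sites are
planted at centres, and the gene body must comfortably hold a 100-segment
profile. The flat-promoter check plants 40 sites uniformly across 25
promoters and bounds the profile's deviation from the uniform CDF by the
Kolmogorov–Smirnov band at α = 0.01 with n = number of sites.

## Known limitations

- The enrichment caller has no FDR control and is not suitable for real
  discovery work; it exists to exercise the downstream stages.
- Genic-region geometry requires at least one base of flank on each side;
  genes flush against a chromosome end are rejected.
- The zero-order motif null understates the expected frequency in genomes
  with dinucleotide structure; fold enrichments on real data should be
  read accordingly.
- The metagene "mainly in zone" selection depends on the coverage
  attribution rule (read counted in every zone it overlaps); other rules
  (midpoint assignment, bp-weighted) would select slightly different gene
  sets.
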