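"""Shared fixtures: the published peak table used to pin the coordinate
convention, and the default simulated dataset."""

from __future__ import annotations

import pytest

from chipscape.synthetic_data import SimulationConfig, simulate_dataset

# The published top-peak table (chromosome, start, end, length, score); the
# printed length pins the 1-based fully-closed coordinate convention.
TABLE_PEAKS = [
    ("1", 82955709, 82956371, 663, 306.0),
    ("7", 1194442, 1195252, 811, 286.97),
    ("1", 76438827, 76439515, 689, 251.83),
    ("5", 4911834, 4912728, 895, 236.06),
    ("5", 4907997, 4908831, 835, 235.12),
    ("9", 4315702, 4316286, 585, 230.55),
    ("1", 89187456, 89187990, 535, 214.65),
    ("8", 61869092, 61869619, 528, 201.54),
    ("3", 59054967, 59055546, 580, 188.78),
    ("9", 58915814, 58916418, 605, 184.69),
    ("6", 41195995, 41196596, 602, 173.86),
    ("2", 46987902, 46988604, 703, 173.8),
    ("2", 48205156, 48205766, 611, 173.8),
    ("12", 6609432, 6610083, 652, 173.8),
    ("12", 64009107, 64009667, 561, 173.51),
]

# The published over-representation table's self-consistent rows:
# (count, printed % in sample, printed % in genome, printed fold).
ENRICHMENT_ROWS = [
    (3, 1.84, 0.12, 15.3),
    (3, 1.84, 0.18, 10.2),
    (23, 14.11, 0.18, 78.4),
]

# Every printed (count, % in sample) pair, used to reconstruct the target-set size.
SAMPLE_PCT_PAIRS = [(4, 2.45), (3, 1.84), (3, 1.84), (4, 2.45), (5, 3.07), (23, 14.11)]


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulation: ~100 kb genome, 20 genes, 10 planted sites,
    enrichment 50 fragments/site over 0.01 fragments/bp background."""
    return simulate_dataset(SimulationConfig())


@pytest.fixture(scope="session")
def centered_body_dataset():
    """A center-planted variant: longer genes, one consensus site at each
    gene-body midpoint, for profile-shape checks."""
    cfg = SimulationConfig(
        genome_length=120_000,
        n_genes=10,
        gene_length_range=(3_000, 4_000),
        site_plan={"gene_body": 10},
    )
    return simulate_dataset(cfg, placement="center")
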