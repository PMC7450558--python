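"""Shared fixtures: synthetic genomes and planted-event datasets.

All fixtures are seed-fixed and generated at test time; nothing is read
from disk.
"""

from __future__ import annotations

import pytest

from cdip import SimulationConfig, generate_genome, simulate_dataset


@pytest.fixture(scope="session")
def genome_2x1mb():
    """Two 1 Mb chromosomes, used for targeted planting tests."""
    return generate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, gc=0.41, seed=7)


@pytest.fixture(scope="session")
def study_dataset():
    """The full study conditions: 20 planted circular-intermediate events
    (20-500 kb donors, divergence up to 7%, full scar spectrum, both
    orientations, mixed intra-/inter-chromosomal) plus 20 decoys."""
    cfg = SimulationConfig(n_csdp=20, n_decoys=20)
    return simulate_dataset(cfg, seed=101)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 5+5-event dataset for pipeline-level tests."""
    cfg = SimulationConfig(
        n_csdp=5,
        n_decoys=5,
        n_chromosomes=3,
        chrom_length=4_000_000,
        size_range=(20_000, 60_000),
        decoy_size_range=(20_000, 40_000),
    )
    return simulate_dataset(cfg, seed=5)
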