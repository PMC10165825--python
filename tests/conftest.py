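import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tfdirect.intervals import GenomicInterval, PeakSet
from tfdirect.simulate import SimulationConfig, simulate_genome, simulate_peaks


def random_peakset(rng, n, factor="F", replicate="rep1", chroms=("chr1", "chr2"),
                   max_pos=100_000, max_width=500):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        ivs.append(
            GenomicInterval(
                chrom=str(rng.choice(chroms)), start=start, end=start + width,
                id=f"{factor}_{replicate}_{i}",
            )
        )
    return PeakSet(factor=factor, replicate=replicate, intervals=ivs)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast configuration: small genome, few genes, low noise."""
    return SimulationConfig(
        seed=7, n_chroms=2, chrom_length_bp=5_000_000, n_genes=200,
        n_cobound_target_genes=24, noise_peaks_per_replicate=20,
        n_noise_interactions=40,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_peaks(small_cfg, small_genome):
    return simulate_peaks(small_cfg, small_genome)


@pytest.fixture
def toy_genes():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+"],
            "tss": [10_000, 60_000, 30_000],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
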