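import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from greekislands.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def config():
    """Default study conditions with a fixed seed."""
    return SimulationConfig(seed=11)


@pytest.fixture
def small_config():
    """A shrunken genome for fast end-to-end exercises."""
    return SimulationConfig(
        seed=11,
        chrom_sizes={"chr1": 3_000_000, "chr2": 2_000_000, "chr3": 1_500_000},
        clusters_per_chrom={"chr1": 2, "chr2": 1, "chr3": 1},
        n_islands=12,
        n_a_only_in=10,
        n_b_only_in=1,
        n_background_peaks=400,
        n_genes=120,
        n_footprint_sites=50,
        n_composite_regions=20,
        n_dispersed_regions=20,
        n_single_site_regions=5,
    )
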