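import numpy as np
import pandas as pd
import pytest

from trisect import SimConfig, simulate_population


@pytest.fixture(scope="session")
def mosaic_sim():
    """316-cell half-trisomic population at deep coverage."""
    cfg = SimConfig(n_genes=100, n_cells_diploid=158, n_cells_trisomic=158,
                    mean_site_depth=20.0, capture_efficiency=0.3, rng_seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def bursty_sim():
    """Low-burst-frequency regime: monoallelic expression dominates."""
    cfg = SimConfig(n_genes=150, n_cells_diploid=300, n_cells_trisomic=300,
                    burst_frequency_range=(0.01, 0.1),
                    mean_site_depth=30.0, capture_efficiency=0.3, rng_seed=5)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def doublet_sim():
    """Diploid population with X sites and 10% doublets."""
    cfg = SimConfig(n_genes=20, n_cells_diploid=120, n_cells_trisomic=0,
                    n_sites_x=40, doublet_rate=0.10, rng_seed=3)
    return simulate_population(cfg)


@pytest.fixture()
def tiny_sites():
    return pd.DataFrame({
        "site_id": ["s1", "s2", "s3"],
        "chrom": ["chr21", "chr21", "chr1"],
        "pos": [100, 200, 300],
        "ref": ["A", "C", "G"],
        "alt": ["G", "T", "A"],
        "gene_id": ["gA", "gA", "gB"],
    })
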