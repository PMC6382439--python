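import numpy as np
import pytest

from tregtraj.synthetic import SimConfig, generate_trajectory_dataset


@pytest.fixture(scope="session")
def nb_dataset():
    """Default-style negative-binomial count dataset with all gene classes."""
    cfg = SimConfig(n_cells_per_group=150, n_switch_genes=40, n_flat_genes=40,
                    n_marker_genes_per_group=15, n_cellcycle_genes=10,
                    n_background_genes=400, seed=42)
    adata, truth = generate_trajectory_dataset(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def gaussian_dataset():
    """Single-axis Gaussian-noise dataset (normalized scale)."""
    cfg = SimConfig(n_cells_per_group=100, n_switch_genes=100, n_flat_genes=0,
                    n_marker_genes_per_group=0, n_cellcycle_genes=0,
                    n_background_genes=0, noise="gaussian", gaussian_sd=0.3, seed=3)
    adata, truth = generate_trajectory_dataset(cfg)
    return cfg, adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
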