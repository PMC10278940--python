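import numpy as np
import pandas as pd
import pytest

from mtm import SimulationConfig, simulate_cohort
from mtm.model import ModelConfig, MTMModel


@pytest.fixture(scope="session")
def small_cohort():
    """60 individuals, 4 tissues, 200 genes, moderate noise."""
    return simulate_cohort(SimulationConfig(
        n_individuals=60, n_tissues=4, n_genes=200,
        latent_dim_static=5, latent_dim_dynamic=3, noise_sd=1.0, seed=1))


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 individuals, 3 tissues, 40 genes — for fast protocol tests."""
    return simulate_cohort(SimulationConfig(
        n_individuals=20, n_tissues=3, n_genes=40,
        latent_dim_static=3, latent_dim_dynamic=2, noise_sd=1.0,
        n_trait_genes=5, n_deg=5, seed=7))


@pytest.fixture()
def tiny_model():
    cfg = ModelConfig(gene_dim=40, tissues=("blood", "tissue_1", "tissue_2"),
                      latent_dim=8, encoder_widths=(16,), noise_dim=4,
                      mapper_widths=(8,), discriminator_widths=(16,), seed=3)
    return MTMModel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
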