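import numpy as np
import pandas as pd
import pytest

from oligopipe.synthetic import (
    BurstSimConfig,
    ExprSimConfig,
    GwasSimConfig,
    simulate_bursts,
    simulate_expression,
    simulate_gwas,
    simulate_ld_blocks,
)


@pytest.fixture(scope="session")
def small_gwas():
    cfg = GwasSimConfig(n_genes=30, snps_per_gene=8, ld_rho=0.5, seed=11)
    blocks = simulate_ld_blocks(cfg)
    gwas, truth = simulate_gwas(cfg, blocks)
    return cfg, blocks, gwas, truth


@pytest.fixture(scope="session")
def planted_expression():
    cfg = ExprSimConfig(
        module_sizes=(40, 40, 40), n_samples=60, within_module_cor=0.8,
        noise_sd=1.0, background_genes=40, seed=5,
    )
    expr, truth = simulate_expression(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def burst_trace():
    cfg = BurstSimConfig(
        n_bins=50_000, background_mean=2.0, monomer_brightness=100.0,
        monomer_event_rate=0.05, oligomer_mass_fraction=0.02,
        true_E=0.65, dust_rate=1e-4, gamma=0.99, seed=3,
    )
    trace, truth = simulate_bursts(cfg)
    return cfg, trace, truth


@pytest.fixture
def uniform_gene_p():
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(100)]
    return dict(zip(genes, rng.uniform(size=100)))
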