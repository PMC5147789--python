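import numpy as np
import pytest

from cohex.simulate import SimulationConfig, simulate_bundle, simulate_expression


@pytest.fixture(scope="session")
def structured_bundle():
    """Small bundle with strong planted structure shared across tests."""
    cfg = SimulationConfig(
        n_genes=400, n_samples_per_dataset={"dsA": 40}, n_pathways=8,
        pathway_size_range=(8, 12), rho=0.9, evidence_noise=0.0,
        phenotype_shift=30.0, seed=2,
    )
    return simulate_bundle(cfg, phenotype_pathway="pwy0000",
                           n_random_mutants=100, n_wild_type=50)


@pytest.fixture(scope="session")
def null_expr():
    """Mutually independent Gaussian genes (no co-expression)."""
    cfg = SimulationConfig(
        n_genes=600, n_samples_per_dataset={"null": 50}, n_pathways=1,
        pathway_size_range=(3, 3), rho=0.0, seed=11,
    )
    expr, _ = simulate_expression(cfg)
    return expr


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
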