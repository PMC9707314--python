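import numpy as np
import pytest

from modtx import SimulationConfig, simulate_cohort, synthetic_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """Three modules of five synthetic genes each."""
    return synthetic_catalog(n_modules=3, genes_per_module=5)


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    """A compact simulated cohort with one shifted/reversed module (M1.2)."""
    cfg = SimulationConfig(
        n_good=12,
        n_non=8,
        n_controls=6,
        catalog=small_catalog,
        disease_shift={"M1.2": 0.5},
        treatment_effect={("M1.2", "good"): -0.5},
        seed=42,
    )
    matrix, metadata, truth = simulate_cohort(cfg)
    return cfg, matrix, metadata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
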