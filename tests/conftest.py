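import numpy as np
import pytest

from molqtl.synthetic import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort shared by read-only tests."""
    config = SimConfig(
        n_individuals=120,
        n_chromosomes=1,
        n_ld_blocks=12,
        variants_per_block=15,
        n_genes=16,
        n_peaks=24,
        n_causal_loci=10,
        n_gwas_credsets=6,
        n_gwas_traits=2,
        seed=7,
    )
    return simulate_cohort(config)
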