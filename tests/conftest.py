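import numpy as np
import pytest

from ccagwas import Effect, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """400 samples, 50 SNPs, two metabolite blocks, one planted effect."""
    cfg = SimulationConfig(
        n_samples_per_cohort=(200, 200),
        n_snps=50,
        network_spec=[(4, 0.7, 0.1), (3, 0.7, 0.1)],
        effect_spec=[Effect(snp_index=0, network_index=0, var_frac=0.05)],
        missing_rate_genotype=0.01,
        seed=7,
    )
    return simulate_dataset(cfg)
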