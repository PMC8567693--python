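import numpy as np
import pytest

from placentamed import synthetic


@pytest.fixture(scope="session")
def small_bundle():
    """A compact calibrated cohort shared by read-only tests: 93 trios,
    60 variants in 20 LD blocks, 12 causal blocks."""
    cfg = synthetic.SimulationConfig(seed=424242, n_blocks=20, block_size=3, n_causal=12)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """One cohort at the full default configuration (3000 variants)."""
    return synthetic.simulate_cohort(synthetic.SimulationConfig(seed=99))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
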