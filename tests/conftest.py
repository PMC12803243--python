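import numpy as np
import pytest

from ras_stability import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def desk_screen():
    """One desk-scale screen with 50 planted destabilizers, shared by
    read-only tests."""
    cfg = simdata.ScreenSimConfig(
        n_genes=300,
        effect_table=simdata.planted_effect_table(300, 15, -1.5),
        n_experiments=2,
        seed=11,
    )
    return cfg, *simdata.simulate_screen(cfg)
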