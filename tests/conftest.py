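import numpy as np
import pytest

import swarminfer as si


@pytest.fixture(scope="session")
def small_zonal_cohesion():
    """A pooled set of small cohesion-state zonal runs (shared across tests)."""
    params = si.ZonalParams(
        N=25, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0, omega_blind=90.0, n_steps=600
    )
    trajs = si.collect_replicates(params, "cohesion", 4, master_seed=11, max_attempts=30)
    return params, trajs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
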