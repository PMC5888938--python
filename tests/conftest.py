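import logging

import numpy as np
import pytest

from hubreserve.synthetic_data import (
    BoldSimParams,
    dian_default_params,
    delcode_default_params,
    simulate_bold_run,
    simulate_cohort,
)

logging.getLogger("hubreserve").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_run():
    """A small simulated run with planted coupling and no motion spikes."""
    params = BoldSimParams(
        grid_shape=(10, 10, 10), n_volumes=120, rng_seed=3,
        coupling_rho=0.35, coupled_fraction=0.5, motion_spike_prob=0.0,
    )
    run, motion, gm, wm, csf = simulate_bold_run(params)
    return dict(params=params, run=run, motion=motion, gm=gm, wm=wm, csf=csf)


@pytest.fixture(scope="session")
def dian_table():
    return simulate_cohort(dian_default_params(rng_seed=42))


@pytest.fixture(scope="session")
def dian_table_info():
    return simulate_cohort(dian_default_params(rng_seed=42), return_info=True)


@pytest.fixture(scope="session")
def delcode_table():
    return simulate_cohort(delcode_default_params(rng_seed=42))


@pytest.fixture(scope="session")
def big_dian_table_info():
    params = dian_default_params(n_per_group={"MC": 250, "NC": 250}, rng_seed=7)
    return simulate_cohort(params, return_info=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
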