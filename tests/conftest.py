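import dataclasses

import numpy as np
import pytest

from choicedyn.synthetic_data import CohortConfig, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """3 rats x 2 sessions x 150 trials: enough structure for every stage."""
    cfg = default_config(seed=11)
    return dataclasses.replace(
        cfg, n_rats=3, n_sessions=2, trials_per_session=150,
        ddm_by_session=cfg.ddm_by_session[:2],
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
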