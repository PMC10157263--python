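import numpy as np
import pytest

import seromark as sm


@pytest.fixture(scope="session")
def small_omics():
    """One small paired-omics draw with a planted marker (shared across tests)."""
    cfg = sm.OmicsSimConfig(n_pairs=200, n_planted=1, seed=11)
    return sm.generate_paired_omics(cfg)


@pytest.fixture(scope="session")
def cohort205():
    """The 205-patient four-class cohort at default study conditions."""
    return sm.generate_cohort(sm.CohortSimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
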