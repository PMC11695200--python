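import numpy as np
import pytest

import dynconn as dc


@pytest.fixture(scope="session")
def small_panel():
    """Six-subject, 120-TR synthetic cohort used by several modules."""
    config = dc.SimConfig(
        n_per_group={"patient": 3, "control": 3}, n_timepoints=120, seed=7
    )
    panel, truth = dc.make_cohort(config)
    return panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
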