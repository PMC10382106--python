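import numpy as np
import pandas as pd
import pytest

import perinorm as pn


@pytest.fixture(scope="session")
def normative_small():
    """Small normative cohort for fast fitting tests."""
    return pn.simulate_normative(n=80, seed=11)


@pytest.fixture(scope="session")
def atlas_small(normative_small):
    """Atlas fitted quickly (single restart) on the small cohort."""
    return pn.NormativeAtlas(n_restarts=1, random_state=0).fit(normative_small)


@pytest.fixture(scope="session")
def atlas_full():
    """Atlas fitted on the reference-size normative cohort (shared across
    the expensive calibration and recovery tests)."""
    train = pn.simulate_normative(n=219, seed=1)
    return pn.NormativeAtlas(n_restarts=4, random_state=0).fit(train)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def score_tables():
    """Tiny hand-built pre/post score tables."""
    pre = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s2"],
            "region": ["brainstem", "cerebellum", "brainstem", "cerebellum"],
            "z": [0.8, -0.2, np.nan, 1.0],
        }
    )
    post = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s2"],
            "region": ["brainstem", "cerebellum", "brainstem", "cerebellum"],
            "z": [0.3, -1.9, -0.5, 1.1],
        }
    )
    return pre, post
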