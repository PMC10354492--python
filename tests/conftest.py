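import numpy as np
import pytest

import micsoc


@pytest.fixture(scope="session")
def study1_config():
    return micsoc.study_config(1)[0]


@pytest.fixture(scope="session")
def study3_config():
    return micsoc.study_config(3)[0]


@pytest.fixture(scope="session")
def study1_dataset():
    """Small study-1 simulation shared across read-only tests."""
    return micsoc.run_study(1, 6, policy="paper_like", master_seed=42)


@pytest.fixture(scope="session")
def study2_dataset():
    return micsoc.run_study(2, 8, policy="paper_like", master_seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
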