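import numpy as np
import pytest

import radon_pt as rp


@pytest.fixture(scope="session")
def windows():
    return rp.default_windows()


@pytest.fixture(scope="session")
def default_campaign():
    """One default synthetic campaign (seed 1): submissions, series, truth."""
    return rp.generate_campaign(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_campaign, windows):
    subs, _, _ = default_campaign
    return rp.run_pipeline(subs, windows)


@pytest.fixture()
def rng():
    return np.random.default_rng(20181105)
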