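import numpy as np
import pytest
from hypothesis import settings

from smcflex import WLCParams, simulate_end_to_end

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_scale_sample():
    """1e5 end-to-end distances at the study's best-fit arm parameters."""
    return simulate_end_to_end(
        WLCParams(persistence_length=3.8, contour_length=46.0, n_chains=100_000, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
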