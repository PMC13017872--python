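import numpy as np
import pytest

from radcell import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def standard_image():
    """One rendered synthetic image pair with foci and micronuclei,
    shared across imaging tests (rendering is the slow part)."""
    cfg = syn.ImageSimConfig(n_nuclei=30, foci_per_nucleus=7,
                             mn_frequency=0.1, seed=101)
    dapi, focus, truth = syn.generate_image_pair(cfg)
    return cfg, dapi, focus, truth
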