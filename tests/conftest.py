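import numpy as np
import pytest

from paovox import phantom


@pytest.fixture(scope="session")
def tiny_model():
    """A small but complete phantom shared by read-only tests."""
    rng = np.random.default_rng(42)
    grid = phantom.GridSpec(16, 24, 24, 0.1)
    params = phantom.VesselTreeParams(n_seeds=3, radius_range_mm=(0.2, 0.3))
    return phantom.random_tissue_model(grid, rng, params=params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
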