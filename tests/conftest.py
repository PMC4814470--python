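import numpy as np
import pytest

from spacerkit.simulate import RepeatModel, make_site_pools


@pytest.fixture(scope="session")
def repeat_model():
    """A 46-bp synthetic repeat with two variants (0.66/0.34) and primers."""
    return RepeatModel.random(seed=11, variant_freqs=(0.66, 0.34))


@pytest.fixture(scope="session")
def single_variant_repeat():
    return RepeatModel.random(seed=12)


@pytest.fixture(scope="session")
def three_site_pools():
    """3 sites x 100 spacers, 30 shared pairwise of which 10 shared by all."""
    return make_site_pools(3, [100, 100, 100], 30, shared_all=10, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
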