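import numpy as np
import pytest
from hypothesis import settings

from hessdenoise import DenoiseParams, PhantomSpec, make_phantom

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def cache_dir(tmp_path):
    d = tmp_path / "spectrum-cache"
    d.mkdir()
    return d


@pytest.fixture
def small_phantom():
    """A (clean, noisy) 16x16x8 filament pair with Gaussian noise SD 0.1."""
    spec = PhantomSpec(shape=(16, 16, 8), n_filaments=3, seed=7)
    return make_phantom(spec)


@pytest.fixture
def fast_params(cache_dir):
    """Few iterations so equivalence runs stay quick."""
    return DenoiseParams(iterations=8, cache_dir=str(cache_dir))
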