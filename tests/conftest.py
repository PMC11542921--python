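import numpy as np
import pytest

from dither.synthetic import make_dictionary, make_retina
from dither.protocols import Fixture


@pytest.fixture(scope="session")
def tiny_fixture() -> Fixture:
    """Small but non-trivial preparation: 4x6 array, 6 ON + 6 OFF cells."""
    array, pop, filt = make_retina(
        rows=4, cols=6, pitch_um=60.0, n_on=6, n_off=6, rf_radius_um=45.0,
        gain=0.3, seed=7, pixel_pitch_um=60.0, grid_shape=(4, 6))
    dic = make_dictionary(array, pop, filt, n_amplitudes=12, seed=8)
    return Fixture(array, pop, filt, dic)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
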