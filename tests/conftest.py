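import numpy as np
import pytest

from dbnlab import RBMParams, gen_bars_stripes, init_rbm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_rbm(rng):
    """3-visible x 2-hidden RBM with non-trivial weights and biases."""
    return RBMParams(
        W=0.3 * rng.standard_normal((3, 2)),
        b_vis=0.1 * rng.standard_normal(3),
        b_hid=0.1 * rng.standard_normal(2),
    )


@pytest.fixture(scope="session")
def bas_2x3():
    return gen_bars_stripes((2, 3), exhaustive=True)


@pytest.fixture(scope="session")
def bas_4x4():
    return gen_bars_stripes(4, exhaustive=True)
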