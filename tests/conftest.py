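import numpy as np
import pytest

from flimcarbon import IRF, TimeAxis, make_irf


@pytest.fixture(scope="session")
def axis() -> TimeAxis:
    return TimeAxis()  # 256 bins over 12.5 ns


@pytest.fixture(scope="session")
def irf(axis) -> IRF:
    return make_irf(fwhm_ps=220.0, axis=axis)


@pytest.fixture(scope="session")
def delta_irf(axis) -> IRF:
    return IRF.delta(axis)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
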