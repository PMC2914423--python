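import numpy as np
import pytest

from cnarray.calibration import SignalCalibration


@pytest.fixture(scope="session")
def cal() -> SignalCalibration:
    return SignalCalibration()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
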