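import numpy as np
import pytest

from dendrocalc import AP_TRAIN, CellGroundTruth


@pytest.fixture
def truth() -> CellGroundTruth:
    """A cell with the generator's default parameters."""
    return CellGroundTruth(seed=11)


@pytest.fixture
def quiet_truth() -> CellGroundTruth:
    """A cell without capacitive transient, for closed-form step checks."""
    return CellGroundTruth(membrane_C_pF=0.0, seed=11)


@pytest.fixture
def train():
    return AP_TRAIN


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
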