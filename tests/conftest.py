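import numpy as np
import pytest

from pedprobe import optics


@pytest.fixture(scope="session")
def vertebra_model() -> optics.LayeredModel:
    return optics.two_layer_vertebra_model()


@pytest.fixture(scope="session")
def probe() -> optics.ProbeGeometry:
    return optics.ProbeGeometry()


@pytest.fixture(scope="session")
def bone_schedule() -> optics.ScanSchedule:
    return optics.ScanSchedule.two_step()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
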