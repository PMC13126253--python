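import numpy as np
import pytest

from nucleotrack.models import MobilityStateModel
from nucleotrack.synthetic import make_geometry


@pytest.fixture(scope="session")
def std_geometry():
    """Exponential-phase-sized spherocylinder at the default pixel size."""
    return make_geometry(3.76, 1.0, 49.0)


@pytest.fixture(scope="session")
def one_state_model():
    return MobilityStateModel(D=[0.1], pi=[1.0], T=[[1.0]], tau=0.04)


@pytest.fixture(scope="session")
def two_state_model():
    """Well-separated sticky two-state model."""
    return MobilityStateModel(
        D=[0.01, 1.0], pi=[0.5, 0.5],
        T=[[0.95, 0.05], [0.05, 0.95]], tau=0.04,
    )
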