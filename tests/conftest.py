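import numpy as np
import pytest

from podosim.fixtures import TrajectoryProfile, make_toe_mesh


@pytest.fixture(scope="session")
def toe():
    """Toe fixture at working resolution (1,280 triangles) with its frame."""
    return make_toe_mesh(subdivision=3)


@pytest.fixture(scope="session")
def toe_mesh(toe):
    return toe[0]


@pytest.fixture(scope="session")
def toe_frame(toe):
    return toe[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def expert_profile():
    return TrajectoryProfile.expert(seed=7)


@pytest.fixture(scope="session")
def novice_profile():
    return TrajectoryProfile.novice(seed=7)
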