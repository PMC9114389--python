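import numpy as np
import pytest

from paleomolar.core import AgeEstimate
from paleomolar.chronomodel import StratEvent


@pytest.fixture(scope="session")
def tnh2_events():
    """The published event set: LU1 silt below, fossil breccia, flowstone
    minimum above."""
    return [
        StratEvent(AgeEstimate(248, 31), unit=0, label="LCC3"),
        StratEvent(AgeEstimate(143, 24), unit=1, label="LCC1"),
        StratEvent(AgeEstimate(133, 19), unit=1, label="LCC2"),
        StratEvent(AgeEstimate(164, 24), unit=1, label="CC10"),
        StratEvent(AgeEstimate(149, 22), unit=1, label="CC11"),
        StratEvent(AgeEstimate(140, 23), unit=1, label="CC12"),
        StratEvent(AgeEstimate(104, 27, role="minimum"), unit=2, label="CCF1"),
    ]


@pytest.fixture(scope="session")
def small_crown():
    """One modest-resolution synthetic crown shared across tests."""
    from paleomolar import synth

    return synth.gen_crown(seed=3)


@pytest.fixture(scope="session")
def landmark_sample():
    """Three well-separated landmark groups, 8 specimens each."""
    from paleomolar import synth

    configs, truth = synth.gen_landmark_groups(n_per_group=8, overlap=0.0,
                                               seed=11)
    return configs, truth


def rigid_copy(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    """Random rotation + scaling + translation of a configuration."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T * rng.uniform(0.5, 2.0) + rng.uniform(-10, 10, 3)
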