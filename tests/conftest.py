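import numpy as np
import pytest

import jointstereo as js


@pytest.fixture(scope="session")
def sphere_phantom() -> js.JointPhantom:
    """Nested-shell sphere: bone 500, cartilage 700, space 800, membrane 850,
    capsule 905 µm."""
    return js.make_phantom((500.0, 700.0, 800.0, 850.0, 905.0))


@pytest.fixture(scope="session")
def study_probes() -> js.ProbeSet:
    return js.ProbeSet(
        area_per_point=23_470.0,
        length_per_point=100.0,
        frame_area=2700.28,
        n_frames=6,
    )


@pytest.fixture(scope="session")
def simulated_specimen(sphere_phantom, study_probes) -> js.SimulatedSpecimen:
    """One fully counted virtual specimen (all probes), fixed seed."""
    return js.simulate_specimen(
        sphere_phantom,
        study_probes,
        js.CellFieldParams(lambda_isolated=1500.0, lambda_parents=60.0),
        50.0,
        20240101,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
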