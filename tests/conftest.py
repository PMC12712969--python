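import numpy as np
import pytest

from femaxis import FemoralNeckAxisModel, FemurSpec, generate_femur


@pytest.fixture(scope="session")
def default_femur():
    """Default noiseless phantom with on-axis head centre."""
    return generate_femur(FemurSpec())


@pytest.fixture(scope="session")
def default_fit(default_femur):
    mesh, truth = default_femur
    return FemoralNeckAxisModel(mesh, truth.landmarks).fit(), truth


@pytest.fixture(scope="session")
def coarse_femur():
    """Coarser phantom used where per-test runtime matters more than fidelity."""
    return generate_femur(FemurSpec(voxel_pitch=2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20190101)
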