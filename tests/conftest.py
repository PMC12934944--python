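import numpy as np
import pytest

from socialrsa import geometry, rdm, synthetic


@pytest.fixture(scope="session")
def model_reps():
    """Three representation sets with the published inter-RDM structure."""
    return synthetic.gen_model_representations(seed=1)


@pytest.fixture(scope="session")
def model_rdms(model_reps):
    return {
        "modelA": rdm.representation_rdm(model_reps["modelA"]),
        "modelB": rdm.representation_rdm(model_reps["modelB"]),
        "behavior": rdm.representation_rdm(model_reps["behavior"]),
    }


@pytest.fixture(scope="session")
def small_grid():
    return geometry.VolumeGrid((8, 8, 8))


@pytest.fixture(scope="session")
def cube_roi(small_grid):
    data = np.zeros(small_grid.shape, dtype=bool)
    data[1:5, 1:5, 1:5] = True
    return geometry.VoxelMask(small_grid, data)
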