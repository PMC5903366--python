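import numpy as np
import pytest

import atlasforge as af


@pytest.fixture(scope="session")
def default_study():
    """One full simulated labeling study (16 regions, 3 observers, 8 templates)."""
    return af.make_study(af.default_study_spec(seed=11))


@pytest.fixture(scope="session")
def fused_atlas(default_study):
    return af.fuse_observer_set(default_study.labels)


@pytest.fixture
def unit_grid():
    """Small 1 mm isotropic grid centred on the mid-sagittal plane."""
    return af.VoxelGrid.create((20, 20, 20), (1.0, 1.0, 1.0), centered=True)


def random_binary_label(grid: af.VoxelGrid, rng: np.random.Generator,
                        p: float = 0.1) -> af.LabeledVolume:
    data = (rng.random(grid.shape) < p).astype(np.uint8)
    return af.LabeledVolume(grid, data, "binary")
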