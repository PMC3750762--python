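import numpy as np
import pytest

from microfuse import (
    ImageGrid,
    PhantomSpec,
    VolumeImage,
    make_phantom,
    simulate_lm_stack,
    simulate_microct,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """Random 8-bit volume on an anisotropic grid."""
    grid = ImageGrid(shape=(8, 9, 10), spacing=(1.5, 0.5, 0.5))
    return VolumeImage(grid=grid, voxels=rng.integers(0, 256, grid.shape,
                                                      dtype=np.uint8))


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom shared by read-only tests."""
    spec = PhantomSpec(seed=1)
    density, labels = make_phantom(spec)
    ct = simulate_microct(density, spec)
    lm, lm_truth = simulate_lm_stack(density, spec)
    return {"spec": spec, "density": density, "labels": labels, "ct": ct,
            "lm": lm, "lm_truth": lm_truth}
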