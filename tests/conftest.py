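import numpy as np
import pytest

from podoquant.scenes import (
    CellSceneSpec,
    LoopSceneSpec,
    NoiseModel,
    generate_cell_scene,
    generate_loop_scene,
)


@pytest.fixture(scope="session")
def loop_scene_half():
    """Noiseless capillary-loop scene with true depth fraction 0.5."""
    spec = LoopSceneSpec(target_depth_fraction=0.5, seed=0)
    image, truth = generate_loop_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def cell_scene_half():
    """Noiseless cultured-cell scene with junction fraction 0.5."""
    spec = CellSceneSpec(junction_fraction=0.5, seed=7)
    image, truth = generate_cell_scene(spec)
    return spec, image, truth


@pytest.fixture
def noisy_spec():
    """Loop-scene spec at SNR 10 (amplitude 1000, gaussian sd 100)."""
    def make(f, seed=0):
        return LoopSceneSpec(
            target_depth_fraction=f,
            noise_model=NoiseModel("gaussian", sd=100.0),
            seed=seed,
        )
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
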