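import numpy as np
import pytest

from cmequant import PatchSceneParams, synth_patch_movie


@pytest.fixture(scope="session")
def noiseless_scene():
    """20-event movie with no noise/bleach; shared across tracking tests."""
    params = PatchSceneParams(n_events=20, noise_sd=0.0, bleach_rate=0.0,
                              diffusion_step_px=0.5, seed=0)
    stack, truth = synth_patch_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Realistic movie: camera noise, photobleaching, post-peak diffusion."""
    params = PatchSceneParams(n_events=20, noise_sd=4.0, bleach_rate=0.002,
                              diffusion_step_px=1.0, seed=1)
    stack, truth = synth_patch_movie(params)
    return params, stack, truth


@pytest.fixture
def triangle_trace():
    """Unit triangle sampled at 1 s: rises 0-10 s, falls 10-20 s."""
    t = np.arange(0.0, 21.0, 1.0)
    return t, np.interp(t, [0.0, 10.0, 20.0], [0.0, 1.0, 0.0])
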