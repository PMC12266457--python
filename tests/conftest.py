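import numpy as np
import pytest

from burntseg import Scene, SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene plus ground truth."""
    params = SceneParams(height=128, width=128, n_burnt_patches=3,
                         patch_scale=20.0, seed=42)
    return generate_scene(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_scene():
    """3x3 scene with hand-set band values for exhaustive lookups."""
    bands = np.zeros((3, 3, 4), dtype=np.float32)
    for r in range(3):
        for c in range(3):
            base = 0.1 * (3 * r + c)
            bands[r, c] = [base, base + 0.01, base + 0.02, base + 0.03]
    return Scene(bands=bands, pixel_size_m=3.0)
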