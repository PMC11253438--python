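import numpy as np
import pytest

from paddydetr.synthetic import SyntheticSceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of deterministic 200-px scenes for IO / metric tests."""
    cfg = SyntheticSceneConfig(
        canvas_size=200,
        n_single=3,
        n_patch=1,
        n_ridge=1,
        single_side=(10, 40),
        patch_side=(60, 90),
        ridge_thickness=(14, 24),
        background_texture=12,
    )
    from dataclasses import replace

    return [generate_scene(replace(cfg, seed=s)) for s in range(5)]
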