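import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from cracksep.synthetic import CrackSpec, SceneSpec, generate_crack_image


@pytest.fixture
def simple_scene() -> SceneSpec:
    """One bright tilted ellipse on a dark, noise-free background."""
    return SceneSpec(
        shape=(128, 128),
        background_intensity=20,
        noise_sigma=0.0,
        cracks=(
            CrackSpec(center=(64.0, 64.0), semi_major=20.0, semi_minor=5.0,
                      orientation_deg=30.0, intensity=200),
        ),
        seed=0,
    )


@pytest.fixture
def simple_image(simple_scene):
    return generate_crack_image(simple_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(20181005)
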