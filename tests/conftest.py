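import numpy as np
import pytest

from tonguecbir.fixtures import PhantomSpec, make_phantom


def solid_rgb(h, s, v, size=(16, 16)):
    """Solid HSV-colored RGB raster (noise-free)."""
    return make_phantom(PhantomSpec(palette=(((h, s, v), 1.0),), size=size))


@pytest.fixture
def rng():
    return np.random.default_rng(20170330)


@pytest.fixture
def stripe_image():
    """High-contrast vertical-stripe phantom, 256x256."""
    return make_phantom(
        PhantomSpec(
            palette=(((350.0, 0.45, 0.85), 1.0),),
            texture="vstripes",
            texture_contrast=160.0,
            size=(256, 256),
            seed=11,
        )
    )
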