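import numpy as np
import pytest

from colorfuzen import ColorImage


def random_image(seed: int, h: int = 10, w: int = 10, k: int = 3,
                 space: str = "generic") -> ColorImage:
    """Seeded uniform-random test image."""
    return ColorImage(np.random.default_rng(seed).random((h, w, k)),
                      space=space)


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
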