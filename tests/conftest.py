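import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_scene():
    """100x100 field at 0.2 with a centered 40x40 square at 0.8, plus the
    coordinates of the square's outer boundary pixels."""
    image = np.full((100, 100), 0.2)
    image[30:70, 30:70] = 0.8
    boundary = set()
    for c in range(30, 70):
        boundary.add((30, c))
        boundary.add((69, c))
    for r in range(30, 70):
        boundary.add((r, 30))
        boundary.add((r, 69))
    return image, np.asarray(sorted(boundary))
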