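import numpy as np
import pytest

from alpinetherm.thermography import ThermalScene


@pytest.fixture
def rng():
    return np.random.default_rng(20230307)


@pytest.fixture
def random_scene_factory(rng):
    """Random thermal scenes with non-trivial masks (never empty/full)."""

    def make(shape=(24, 32)):
        grid = rng.normal(20.0, 5.0, size=shape)
        mask = rng.random(shape) < 0.4
        mask.flat[0] = True  # never empty
        mask.flat[-1] = False  # never full
        return ThermalScene(grid=grid, plant_mask=mask)

    return make


def disk_mask(n: int, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2
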