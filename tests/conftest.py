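import numpy as np
import pytest

from mycosole import ConductiveTemplate


@pytest.fixture
def full_3x3():
    return ConductiveTemplate(np.ones((3, 3), dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20230321)


def random_template(rng, shape=(20, 20), p=0.6):
    """Random masked template guaranteed non-empty."""
    grid = rng.random(shape) < p
    if not grid.any():
        grid[shape[0] // 2, shape[1] // 2] = True
    return ConductiveTemplate(grid)
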