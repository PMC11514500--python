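import numpy as np
import pytest

from mitohotspot import PolygonMM, RunConfig


@pytest.fixture
def unit_square() -> PolygonMM:
    return PolygonMM(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


def random_instance(seed: int, n_max: int = 12, field: float = 3.0):
    """A random BAME test instance: points in a square field plus a bound."""
    r = np.random.default_rng(seed)
    n = int(r.integers(3, n_max + 1))
    pts = r.uniform(0.0, field, size=(n, 2))
    bound = float(r.uniform(0.1 * field, field))
    return pts, bound
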