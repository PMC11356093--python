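import numpy as np
import pytest

from morphoglue import Grid, TargetPattern, make_pattern


@pytest.fixture(scope="session")
def face30() -> TargetPattern:
    return make_pattern("face", 30)


@pytest.fixture(scope="session")
def face12() -> TargetPattern:
    return make_pattern("face", 12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_grid(n: int, seed: int, p: float = 0.5) -> Grid:
    cells = (np.random.default_rng(seed).random((n, n)) < p).astype(np.uint8)
    return Grid(cells)
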