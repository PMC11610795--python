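import numpy as np
import pytest

from tacmix import (
    DiscreteMeasure,
    NoiseModel,
    OperatorCache,
    ParamDomain,
    ParameterGrid,
)


@pytest.fixture(scope="session")
def default_grid() -> ParameterGrid:
    """The 20x20 study grid on [0.05, 1]^2."""
    return ParameterGrid(ParamDomain(), 20, 20)


@pytest.fixture(scope="session")
def small_grid() -> ParameterGrid:
    return ParameterGrid(ParamDomain(0.2, 0.8, 0.2, 0.8), 3, 3)


@pytest.fixture(scope="session")
def shared_cache() -> OperatorCache:
    """Session-wide operator cache; results do not depend on cache state."""
    return OperatorCache()


@pytest.fixture(scope="session")
def noise() -> NoiseModel:
    return NoiseModel(1e-6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_simplex(rng: np.random.Generator, M: int) -> np.ndarray:
    w = rng.exponential(size=M)
    return w / w.sum()


@pytest.fixture
def two_atom_measure(default_grid) -> DiscreteMeasure:
    ja = default_grid.nearest_index((0.3, 0.4))
    jb = default_grid.nearest_index((0.6, 0.75))
    return DiscreteMeasure.atoms(default_grid, [ja, jb], [0.3, 0.7])
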