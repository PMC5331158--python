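import math

import numpy as np
import pytest

from ramadens import (
    CollectiveDensityEstimator,
    DirectionSpec,
    SyntheticSpec,
    TensorBasis,
    generate_shared_basis,
)


@pytest.fixture(scope="session")
def torus_basis() -> TensorBasis:
    """Small fully periodic tensor basis used across unit tests."""
    d = DirectionSpec(periodic=True, df=8, order=4)
    return TensorBasis(d, d, diff_order=2, cyclic_penalty=True, grid_points=30)


@pytest.fixture(scope="session")
def mixed_basis() -> TensorBasis:
    """Bounded-theta / periodic-tau domain basis."""
    d1 = DirectionSpec(periodic=False, df=5, order=4,
                       range=(math.radians(75), math.radians(165)))
    d2 = DirectionSpec(periodic=True, df=10, order=4)
    return TensorBasis(d1, d2, diff_order=2, cyclic_penalty=True,
                       grid_points=30)


@pytest.fixture(scope="session")
def small_shared_data():
    """Two-cluster synthetic dataset from the shared-basis model."""
    spec = SyntheticSpec(m=6, n_i=80, K_true=2, n_clusters=2,
                         separation=3.0, seed=5, df=(8, 8), grid_points=40)
    return generate_shared_basis(spec)


@pytest.fixture(scope="session")
def small_fit(small_shared_data):
    """Collective fit on the small synthetic dataset (reused; read-only)."""
    data, truths, labels = small_shared_data
    est = CollectiveDensityEstimator(
        n_components=2, dir1=DirectionSpec(df=8), dir2=DirectionSpec(df=8),
        grid_points=40, max_iter=200,
    )
    est.fit_dataset(data)
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
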