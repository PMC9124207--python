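import numpy as np
import pandas as pd
import pytest

from metsom.synthetic_data import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 3,000-participant default cohort shared across read-only tests."""
    return generate_cohort(default_config(3000, seed=11))


@pytest.fixture(scope="session")
def clustered_data():
    """Six well-separated Gaussian clusters (between-centroid distance ~6 SD)
    in 33 dimensions, n = 3,000 — a planted structure the map must find."""
    rng = np.random.default_rng(42)
    k, dim, n = 6, 33, 3000
    centers = rng.normal(0, 1, (k, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= 4.5  # near-orthogonal directions -> pairwise distance ~ 6.4 SD
    labels = rng.integers(0, k, n)
    X = centers[labels] + rng.normal(0, 1, (n, dim))
    df = pd.DataFrame(X, index=[f"P{i}" for i in range(n)])
    df.columns = [f"x{j}" for j in range(dim)]
    return df, labels
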