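import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_distance_matrix(rng, n):
    """A random symmetric, zero-diagonal, nonnegative matrix."""
    M = rng.uniform(0.1, 5.0, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


@pytest.fixture
def expression_frame(rng):
    """Small subjects x genes frame with named ids."""
    values = rng.standard_normal((20, 6))
    return pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(20)],
        columns=[f"gene{j}" for j in range(6)],
    )
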