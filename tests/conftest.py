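import numpy as np
import pandas as pd
import pytest

from steeprank.dominance import InteractionMatrix, validate_matrix


@pytest.fixture
def abc_matrix() -> InteractionMatrix:
    """A beats B 2-0, A beats C 2-0, B beats C 2-0."""
    df = pd.DataFrame(
        [[0, 2, 2], [0, 0, 2], [0, 0, 0]], index=list("ABC"), columns=list("ABC")
    )
    return validate_matrix(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_matrix(n: int, seed, max_count: int = 10) -> InteractionMatrix:
    """Random non-negative sociomatrix (not from the logistic model)."""
    gen = np.random.default_rng(seed)
    counts = gen.integers(0, max_count + 1, size=(n, n))
    np.fill_diagonal(counts, 0)
    return InteractionMatrix(
        ids=tuple(f"i{k}" for k in range(n)), counts=counts.astype(np.int64)
    )


def linear_matrix(n: int, wins: int) -> InteractionMatrix:
    """Perfect-information linear hierarchy: i beats j for all i < j."""
    counts = np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    counts[iu, ju] = wins
    return InteractionMatrix(ids=tuple(f"i{k}" for k in range(n)), counts=counts)
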