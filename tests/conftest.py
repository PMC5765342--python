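import numpy as np
import pytest

from phenorec import RatingMatrix, SimilarityMatrix

ITEMS = ["I1", "I2", "I3"]
USERS = ["U1", "U2", "U3", "U4"]


@pytest.fixture
def toy_ratings() -> RatingMatrix:
    """The 4-user × 3-item ordinal rating matrix with three missing cells."""
    values = np.array(
        [
            [2.0, np.nan, 3.0],
            [5.0, 2.0, np.nan],
            [3.0, 3.0, 1.0],
            [np.nan, 2.0, 2.0],
        ]
    )
    return RatingMatrix(list(USERS), list(ITEMS), values, np.isfinite(values))


@pytest.fixture
def toy_similarity() -> SimilarityMatrix:
    """The published item–item cosine weights for the toy rating matrix."""
    W = np.array(
        [
            [1.00, 0.76, 0.78],
            [0.76, 1.00, 0.86],
            [0.78, 0.86, 1.00],
        ]
    )
    return SimilarityMatrix(list(ITEMS), W, np.full((3, 3), 4, dtype=int), "external")


def random_rating_matrix(
    rng: np.random.Generator,
    max_rows: int = 8,
    max_cols: int = 6,
    missing_frac: float = 0.3,
) -> RatingMatrix:
    """Small random matrix with random missingness; every row/col keeps ≥1 cell."""
    n = rng.integers(2, max_rows + 1)
    m = rng.integers(2, max_cols + 1)
    values = rng.normal(size=(n, m))
    mask = rng.random((n, m)) >= missing_frac
    # keep at least one observed cell per row and per column
    for i in range(n):
        if not mask[i].any():
            mask[i, rng.integers(m)] = True
    for j in range(m):
        if not mask[:, j].any():
            mask[rng.integers(n), j] = True
    values[~mask] = np.nan
    rows = [f"g{i}" for i in range(n)]
    cols = [f"E1_T{j}" for j in range(m)]
    return RatingMatrix(rows, cols, values, mask)
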