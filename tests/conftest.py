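import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from culturedrift import (
    Code,
    DiagonalPolicy,
    PairwiseMatrix,
    Polarity,
    TraitTable,
    make_plains_fixture,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def plains_layout():
    return make_plains_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_distance_matrix(rng, n, labels=None):
    """Random symmetric distance matrix with zero diagonal."""
    x = rng.random((n, n))
    d = (x + x.T) / 2.0
    np.fill_diagonal(d, 0.0)
    labels = labels or [f"g{i}" for i in range(n)]
    return PairwiseMatrix(labels, d, Polarity.DISTANCE, DiagonalPolicy.ZERO)


def random_trait_table(rng, n_groups=9, n_traits=82, p_questionable=0.05):
    """Random trait table with a sprinkling of questionable cells."""
    cells = np.where(rng.random((n_groups, n_traits)) < 0.5, 1, 0).astype(np.int8)
    q = rng.random((n_groups, n_traits)) < p_questionable
    cells[q] = int(Code.QUESTIONABLE)
    return TraitTable(
        [f"g{i}" for i in range(n_groups)],
        [f"t{j}" for j in range(n_traits)],
        cells,
    )


def jaccard_bruteforce(row_i, row_j, pairwise_delete=True):
    """Independent set-based Jaccard oracle for one pair of code rows."""
    a = b = c = d = deleted = 0
    for u, v in zip(row_i.tolist(), row_j.tolist()):
        if pairwise_delete and (u == -1 or v == -1):
            deleted += 1
            continue
        if not pairwise_delete:
            u = 1 if u == -1 else u
            v = 1 if v == -1 else v
        if u == 1 and v == 1:
            a += 1
        elif u == 1:
            b += 1
        elif v == 1:
            c += 1
        else:
            d += 1
    return a, b, c, d, deleted
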