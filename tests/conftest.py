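import numpy as np
import pytest

from guildassembly.tabular_io import DistanceMatrix, OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([[5, 3, 0, 2],
                       [1, 0, 4, 5],
                       [2, 2, 2, 4]])
    return OtuTable(("s1", "s2", "s3"), ("o1", "o2", "o3", "o4"), counts)


def random_table(rng: np.random.Generator, n_samples: int = 5,
                 n_otus: int = 8, max_count: int = 50) -> OtuTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    counts[:, 0] += 1  # no all-zero rows
    return OtuTable(tuple(f"s{i}" for i in range(n_samples)),
                    tuple(f"o{j}" for j in range(n_otus)), counts)


def random_distance_matrix(rng: np.random.Generator, n: int,
                           labels=None) -> DistanceMatrix:
    """Distances between random points on a line: valid metric, full rank."""
    pts = rng.uniform(0, 10, n)
    vals = np.abs(pts[:, None] - pts[None, :])
    if labels is None:
        labels = tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(tuple(labels), vals)


def signed_matrix_from_condensed(labels, condensed) -> DistanceMatrix:
    return DistanceMatrix.from_condensed(labels, np.asarray(condensed, float),
                                         signed=True)
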