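import numpy as np
import pytest

from clustagg.datatypes import (
    AnnotationMap,
    CandidateKey,
    DataMatrix,
    DistanceMatrix,
    Partition,
)


@pytest.fixture
def line_matrix() -> DataMatrix:
    """Four points on a line at 0, 1, 10, 11: two obvious pairs."""
    return DataMatrix(
        np.array([[0.0], [1.0], [10.0], [11.0]]),
        ["a", "b", "c", "d"],
        ["x"],
    )


@pytest.fixture
def line_dist(line_matrix) -> DistanceMatrix:
    from clustagg.partition import compute_distance

    return compute_distance(line_matrix, "euclidean")


@pytest.fixture
def line_partition() -> Partition:
    return Partition(CandidateKey("pam", 2), np.array([1, 1, 2, 2]))


@pytest.fixture
def line2_matrix() -> DataMatrix:
    """The line fixture with its column duplicated (stability hand traces)."""
    v = np.array([[0.0], [1.0], [10.0], [11.0]])
    return DataMatrix(np.hstack([v, v]), ["a", "b", "c", "d"], ["x", "y"])
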