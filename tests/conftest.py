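import numpy as np
import pandas as pd
import pytest

from connectodiff import (
    CohortManifest,
    ConnectomeMatrix,
    NodeTable,
    WeightKind,
)


@pytest.fixture
def triangle() -> ConnectomeMatrix:
    """3-node triangle with w12=1, w13=2, w23=3 (strengths 3, 4, 5)."""
    w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    return ConnectomeMatrix("s1", WeightKind.LOG_SIFT2, w, ["a", "b", "c"])


@pytest.fixture
def path_graph() -> ConnectomeMatrix:
    """Path A-B-C with unit weights."""
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return ConnectomeMatrix("s1", WeightKind.LOG_SIFT2, w, ["A", "B", "C"])


@pytest.fixture
def small_manifest() -> CohortManifest:
    return CohortManifest(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(5)],
                "group": ["A", "A", "A", "B", "B"],
                "age": [20.0, 22.0, 24.0, 26.0, 28.0],
                "sex": ["M", "F", "M", "F", "M"],
                "dup_weeks": [10.0, np.nan, 30.0, 12.0, 8.0],
            }
        )
    )


@pytest.fixture
def node_table_lr() -> NodeTable:
    return NodeTable(
        pd.DataFrame(
            {
                "node_id": ["a", "b", "c", "d"],
                "name": ["ra", "rb", "rc", "rd"],
                "hemisphere": ["L", "L", "R", "R"],
                "lobe": ["frontal"] * 4,
            }
        )
    )


def make_matrix(w: np.ndarray, subject_id: str = "s", kind=WeightKind.LOG_SIFT2):
    n = w.shape[0]
    return ConnectomeMatrix(subject_id, kind, w, [f"n{i}" for i in range(n)])
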