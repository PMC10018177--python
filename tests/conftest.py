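import numpy as np
import pandas as pd
import pytest

from effdyn.panel import PanelDataset, SpatialWeights, VariableInfo


@pytest.fixture
def tiny_schema():
    return {
        "staff": VariableInfo("input", "human"),
        "beds": VariableInfo("input", "non_human"),
        "residents": VariableInfo("output", "other"),
    }


@pytest.fixture
def tiny_panel(tiny_schema):
    """3 units x 2 years x 3 variables, all positive."""
    rows = []
    values = {
        ("A", 2019): (2.0, 3.0, 4.0), ("A", 2020): (2.0, 3.0, 5.0),
        ("B", 2019): (4.0, 5.0, 4.0), ("B", 2020): (4.0, 5.0, 4.0),
        ("C", 2019): (8.0, 9.0, 4.0), ("C", 2020): (8.0, 9.0, 3.0),
    }
    for (unit, year), (staff, beds, res) in values.items():
        rows += [(unit, year, "staff", staff), (unit, year, "beds", beds),
                 (unit, year, "residents", res)]
    return PanelDataset(
        pd.DataFrame(rows, columns=["unit", "year", "variable", "value"]),
        tiny_schema,
    )


@pytest.fixture
def path_graph_w():
    """3-node path graph 1-2-3 (binary contiguity)."""
    m = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return SpatialWeights(["n1", "n2", "n3"], m)


@pytest.fixture
def checkerboard_w():
    """2x2 rook grid: cells (0,0),(0,1),(1,0),(1,1)."""
    m = np.array(
        [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], dtype=float
    )
    return SpatialWeights(["c00", "c01", "c10", "c11"], m)


@pytest.fixture
def ring4_w():
    """4-cycle in ring order."""
    m = np.array(
        [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=float
    )
    return SpatialWeights(["r1", "r2", "r3", "r4"], m)


@pytest.fixture
def grid5_w():
    """5x5 rook grid (25 units)."""
    n = 5
    ids = [f"g{i}{j}" for i in range(n) for j in range(n)]
    m = np.zeros((n * n, n * n))
    for i in range(n):
        for j in range(n):
            a = i * n + j
            if i + 1 < n:
                m[a, (i + 1) * n + j] = m[(i + 1) * n + j, a] = 1
            if j + 1 < n:
                m[a, i * n + j + 1] = m[i * n + j + 1, a] = 1
    return SpatialWeights(ids, m)
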