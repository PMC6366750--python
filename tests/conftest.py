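import numpy as np
import pandas as pd
import pytest

from oscpls.datamatrix import TaskDataMatrix


def make_task_matrix(
    X: np.ndarray,
    n_groups: int = 1,
    n_conditions: int = 2,
    group_names: tuple[str, ...] | None = None,
    condition_names: tuple[str, ...] | None = None,
) -> TaskDataMatrix:
    """Wrap a raw matrix as a TaskDataMatrix with a balanced design.

    Rows of X must already be ordered group-major, condition within group,
    subject within condition.
    """
    n_rows, n_cols = X.shape
    per_cell = n_rows // (n_groups * n_conditions)
    assert per_cell * n_groups * n_conditions == n_rows
    groups = group_names or tuple(f"g{i + 1}" for i in range(n_groups))
    conds = condition_names or tuple(f"c{i + 1}" for i in range(n_conditions))
    rows = []
    for gi, g in enumerate(groups):
        for c in conds:
            for s in range(per_cell):
                rows.append({"subject": f"{g}_s{s}", "group": g, "condition": c})
    cols = pd.DataFrame(
        {"channel": [f"ch{i}" for i in range(n_cols)], "band": ["b"] * n_cols}
    )
    return TaskDataMatrix(
        X=X, rows=pd.DataFrame(rows), cols=cols, groups=groups, conditions=conds
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
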