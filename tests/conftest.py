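import numpy as np
import pandas as pd
import pytest

from reclasskappa.core import ExpectedTable, ReclassTable


@pytest.fixture
def worked_counts():
    """Observed counts of the 50-subject worked example."""
    return dict(a=20, b=5, c=5, d=5, e=5, f=10)


@pytest.fixture
def worked_table(worked_counts):
    return ReclassTable.from_counts(**worked_counts)


@pytest.fixture
def worked_tables(worked_table):
    return worked_table, ExpectedTable.from_observed(worked_table)


def make_worked_pairs() -> pd.DataFrame:
    """50 risk pairs engineered to reproduce the worked example's table.

    Direction is driven purely by p_new relative to p_base = 0.5; cell
    counts follow the (direction x outcome) layout a=20, b=5, c=5, d=5,
    e=5, f=10.
    """
    rows = []
    cells = [  # (count, outcome, p_new)
        (20, 0, 0.4),  # a: disease-free, down
        (5, 1, 0.4),   # b: diseased, down
        (5, 0, 0.5),   # c: disease-free, none
        (5, 1, 0.5),   # d: diseased, none
        (5, 0, 0.6),   # e: disease-free, up
        (10, 1, 0.6),  # f: diseased, up
    ]
    sid = 0
    for count, outcome, p_new in cells:
        for _ in range(count):
            sid += 1
            rows.append({"subject_id": sid, "outcome": outcome,
                         "p_base": 0.5, "p_new": p_new})
    return pd.DataFrame(rows)


@pytest.fixture
def worked_pairs():
    return make_worked_pairs()


def random_table(rng: np.random.Generator, n_max: int = 400) -> ReclassTable:
    """A random non-degenerate reclassification table."""
    while True:
        counts = rng.integers(0, n_max // 6 + 1, size=6)
        t = ReclassTable(*[int(c) for c in counts])
        if t.n_healthy > 0 and t.n_diseased > 0 and t.n >= 4:
            return t


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
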