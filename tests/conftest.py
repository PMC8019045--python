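import datetime as dt

import numpy as np
import pytest

from multisoc.association import AssociationMatrix
from multisoc.io import ScanRecord


def scan(date, focal, associates=(), time=dt.time(9, 0)):
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    return ScanRecord(date=date, time=time, focal_unit=focal, associates=frozenset(associates))


def matrix_from_square(units, square, n_scans=100):
    """AssociationMatrix from a square AI array; provenance counts are
    synthesized to be consistent (joint = ai * n_scans, totals = n_scans)."""
    ai = np.asarray(square, dtype=float)
    np.fill_diagonal(ai, np.nan)
    joint = np.nan_to_num(ai * n_scans).astype(np.int64)
    totals = np.full(len(units), n_scans, dtype=np.int64)
    return AssociationMatrix(list(units), ai, joint, totals)


@pytest.fixture
def toy_scans():
    """A and B together in 2 of 4 scans, once each alone; C never sighted."""
    return [
        scan("2018-01-01", "A", {"B"}),
        scan("2018-01-02", "B", {"A"}),
        scan("2018-01-03", "A"),
        scan("2018-01-04", "B"),
    ]


@pytest.fixture
def block_matrix():
    """Two 2-unit blocks: within-pair AI 0.3, cross 0.01 (ultrametric)."""
    square = [
        [0.0, 0.3, 0.01, 0.01],
        [0.3, 0.0, 0.01, 0.01],
        [0.01, 0.01, 0.0, 0.3],
        [0.01, 0.01, 0.3, 0.0],
    ]
    return matrix_from_square(["a", "b", "c", "d"], square)


@pytest.fixture
def chain_matrix():
    """a-b strong, b-c medium, a-c weak: separates single from complete."""
    square = [
        [0.0, 0.5, 0.1],
        [0.5, 0.0, 0.4],
        [0.1, 0.4, 0.0],
    ]
    return matrix_from_square(["a", "b", "c"], square)
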