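import numpy as np
import pytest

from dmsensemble.bitvectors import BitMatrix
from dmsensemble.reference import ReferenceWindow

_CODE = {"0": 0, "1": 1, "?": 2}


def matrix_from_strings(window: ReferenceWindow, rows: list[str], weights=None) -> BitMatrix:
    """Build a BitMatrix from code strings like '01?0' (0 match, 1 mutation,
    ? uninformative)."""
    codes = np.array([[_CODE[c] for c in row] for row in rows], dtype=np.int8)
    ids = [f"r{i}" for i in range(len(rows))]
    return BitMatrix(window, codes, ids, weights)


@pytest.fixture
def small_window() -> ReferenceWindow:
    # 10-nt window, A/C at positions 1,2,4,6,7,9 (1-based)
    return ReferenceWindow("toy", "ACGAGACCGC", 1, 10)


@pytest.fixture
def hairpin_window() -> ReferenceWindow:
    return ReferenceWindow("hp", "GGAAACC", 1, 7)
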