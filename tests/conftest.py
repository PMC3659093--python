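import numpy as np
import pytest

from tmakit.registry import load_default_cdes
from tmakit.slidemap import RecipientBlock, SlideMap, parse_layout_table


@pytest.fixture(scope="session")
def registry():
    return load_default_cdes()


@pytest.fixture()
def block_3x3():
    return RecipientBlock(block_id="B1", n_cols=3, n_rows=3)


@pytest.fixture()
def slidemap_3x3(block_3x3) -> SlideMap:
    """3x3 layout: one gap at (2,1), one marker at (3,1), donor DB1 replicated."""
    rows = [
        ["DB1", "", "MARKER"],
        ["DB2", "DB1", "DB3"],
        ["DB4", "DB5", "DB6"],
    ]
    return parse_layout_table(rows, block_3x3, "S1", marker_name="ER")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130501)


def random_slidemap(rng: np.random.Generator, slide_id: str = "S1") -> SlideMap:
    """Random layout for round-trip properties (shared across test modules)."""
    n_cols = int(rng.integers(1, 6))
    n_rows = int(rng.integers(1, 6))
    rows = []
    for _ in range(n_rows):
        row = []
        for _ in range(n_cols):
            u = rng.uniform()
            if u < 0.15:
                row.append("")
            elif u < 0.25:
                row.append("MARKER")
            else:
                row.append(f"DB{int(rng.integers(1, 40)):03d}")
        rows.append(row)
    block = RecipientBlock(
        block_id=f"B{int(rng.integers(1, 100))}",
        n_cols=n_cols,
        n_rows=n_rows,
        core_diameter=float(np.round(rng.uniform(0.1, 2.0), 3)),
        core_spacing=float(np.round(rng.uniform(0.2, 3.0), 3)),
        slice_number=int(rng.integers(1, 20)),
    )
    return parse_layout_table(rows, block, slide_id, marker_name="ER")
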