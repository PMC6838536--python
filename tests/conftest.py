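import numpy as np
import pandas as pd
import pytest

from crosstalker import ExpressionProfile, LRDatabase, SingleCellMatrix


@pytest.fixture
def toy_profile() -> ExpressionProfile:
    """Two populations, one ligand expressed in A only, one receptor in both."""
    data = pd.DataFrame(
        {
            "A": [50.0, 30.0, 2.0],
            "B": [1.0, 40.0, 3.0],
        },
        index=["L1", "R1", "Bg1"],
    )
    return ExpressionProfile(data)


@pytest.fixture
def toy_lrdb() -> LRDatabase:
    return LRDatabase(pairs=frozenset({("L1", "R1")}))


@pytest.fixture
def toy_matrix() -> SingleCellMatrix:
    """Six cells over four genes with cell totals straddling a boundary."""
    counts = pd.DataFrame(
        np.array(
            [
                [500, 700, 1000, 0, 2, 10],
                [500, 401, 1000, 0, 3, 10],
                [300, 200, 500, 0, 0, 10],
                [200, 200, 500, 0, 1, 10],
            ]
        ),
        index=["g1", "g2", "g3", "g4"],
        columns=[f"c{i}" for i in range(1, 7)],
    )  # cell totals: 1500, 1501, 3000, 0, 6, 40
    gates = pd.Series({f"c{i}": "gateA" if i <= 3 else "gateB" for i in range(1, 7)})
    return SingleCellMatrix(counts=counts, gate_labels=gates)
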