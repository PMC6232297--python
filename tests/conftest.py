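import numpy as np
import pandas as pd
import pytest

from reservoirnet.containers import EnvTable, OTUTable


@pytest.fixture
def small_otu_table() -> OTUTable:
    counts = pd.DataFrame(
        [[10, 30, 60, 0], [25, 25, 25, 25], [100, 0, 0, 0]],
        index=pd.Index(["s1", "s2", "s3"], name="sample"),
        columns=["OTU_1", "OTU_2", "OTU_3", "OTU_4"],
    )
    meta = pd.DataFrame(
        {"reservoir": ["A", "A", "A"], "site": ["x", "x", "y"],
         "month": [1, 2, 3]},
        index=counts.index,
    )
    return OTUTable(counts, metadata=meta)


@pytest.fixture
def env_table() -> EnvTable:
    values = pd.DataFrame(
        {"TN": [1.0, 2.0, 3.0], "TP": [0.5, np.nan, 0.7],
         "temperature": [10.0, 20.0, 30.0]},
        index=pd.Index(["s1", "s2", "s3"], name="sample"),
    )
    return EnvTable(values)


def euclid_matrix(points: np.ndarray):
    """Plain Euclidean distance ResemblanceMatrix on row-vectors."""
    from reservoirnet.resemblance import EUCLIDEAN, ResemblanceMatrix

    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(len(points))]
    return ResemblanceMatrix(ids, d, EUCLIDEAN)
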