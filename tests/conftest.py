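import numpy as np
import pandas as pd
import pytest

from normsvr import Dataset, FeatureTable, join_dataset


def make_meta(rows):
    return pd.DataFrame(rows, columns=["sample_id", "role", "batch", "region", "acq_order"])


@pytest.fixture
def tiny_dataset():
    """Six samples (4 QC, 2 cells), three features, hand-checkable numbers."""
    intensities = pd.DataFrame(
        {
            "mz_100.0": [4.0, 6.0, 5.0, 5.0, 10.0, 2.0],
            "mz_200.0": [10.0, 10.0, 12.0, 8.0, 30.0, 1.0],
            "mz_300.0": [7.0, 7.0, 7.0, 7.0, 7.0, 7.0],
        },
        index=["q1", "q2", "q3", "q4", "c1", "c2"],
    )
    meta = make_meta(
        [
            ("q1", "qc", "b1", "r1", 0),
            ("q2", "qc", "b1", "r1", 2),
            ("q3", "qc", "b1", "r2", 4),
            ("q4", "qc", "b1", "r2", 6),
            ("c1", "cell", "b1", "r1", 1),
            ("c2", "cell", "b1", "r2", 3),
        ]
    )
    return join_dataset(FeatureTable(intensities), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
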