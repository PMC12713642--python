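import numpy as np
import pandas as pd
import pytest

from phyllocore.io_prep import HABITATS, AbundanceTable, SampleMetadata


@pytest.fixture
def balanced_meta():
    """3 habitats x 2 sites x 4 replicates, constant covariates."""
    rows = []
    for hab in HABITATS:
        for site in "AB":
            for rep in range(4):
                rows.append(
                    {
                        "sample_id": f"{hab}_{site}{rep}",
                        "habitat": hab,
                        "site": site,
                        "plot": f"{site}{rep}",
                        "pH": 5.0,
                        "elevation": 100.0,
                    }
                )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def toy_counts():
    """3 samples x 4 taxa integer counts."""
    data = pd.DataFrame(
        [[5, 0, 2, 3], [1, 1, 0, 8], [4, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
        dtype=float,
    )
    return AbundanceTable(data, mode="counts")


def make_relative(matrix, prefix_s="s", prefix_t="t") -> AbundanceTable:
    arr = np.asarray(matrix, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        arr,
        index=[f"{prefix_s}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_t}{j}" for j in range(arr.shape[1])],
    )
    return AbundanceTable(df, mode="relative")
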