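import numpy as np
import pandas as pd
import pytest

from vanadiome.tables import CommunityTable


@pytest.fixture
def small_counts_table():
    data = pd.DataFrame(
        [[4, 3, 2, 1], [1, 0, 5, 2], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3", "f4"],
    )
    return CommunityTable(data, feature_kind="taxon", mode="counts")


@pytest.fixture
def small_meta():
    return pd.DataFrame(
        {
            "habitat": ["gut", "gut", "soil"],
            "dose": [0.0, 100.0, 0.0],
            "replicate": [1, 2, 1],
            "group_label": ["GV0", "GV1", "SV0"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
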