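import numpy as np
import pandas as pd
import pytest

from pollenpref import ExpressionMatrix, SampleMetadata


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples: two anther replicates, two late-pollen replicates."""
    values = np.array([
        [5.0, 5.2, 9.0, 9.2],
        [7.0, 7.2, 7.1, 6.9],
        [8.0, 8.4, 4.0, 4.2],
    ])
    return ExpressionMatrix(["p1", "p2", "p3"],
                            ["s_anther_1", "s_anther_2", "s_mp_1", "s_mp_2"],
                            values)


@pytest.fixture
def small_metadata():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s_anther_1", "s_anther_2", "s_mp_1", "s_mp_2"],
        "cultivar": ["japonica"] * 4,
        "tissue_group": ["anther", "anther", "pollen", "pollen"],
        "stage_label": ["Me", "Me", "MP", "MP"],
        "stage_order": [0, 0, 1, 1],
        "is_late_pollen": [False, False, True, True],
    }))


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    n, m = 30, 8
    return ExpressionMatrix(
        [f"p{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        rng.normal(7.0, 1.0, size=(n, m)),
    )
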