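import numpy as np
import pandas as pd
import pytest

from cellcomm.io import ExpressionMatrix, SampleMetadata


@pytest.fixture
def small_counts():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[5.0, 0.0], [3.0, 7.0], [2.0, 3.0]]),
        unit="counts",
    )


@pytest.fixture
def two_group_meta():
    return SampleMetadata(
        pd.DataFrame(
            {"condition": ["ctrl", "ctrl", "ctrl", "lps", "lps", "lps"]},
            index=[f"s{i}" for i in range(1, 7)],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
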