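import numpy as np
import pandas as pd
import pytest

from spatiophylo.features import FeatureMatrix


def make_matrix(rows: dict[str, list], features: list[str]) -> FeatureMatrix:
    """FeatureMatrix from {taxon: values} with None for missing."""
    data = pd.DataFrame.from_dict(rows, orient="index", columns=features)
    return FeatureMatrix(data.astype(float))


@pytest.fixture
def toy_matrix() -> FeatureMatrix:
    return make_matrix(
        {
            "alpha": [1, 0, 1, 1],
            "bravo": [1, 0, 1, None],
            "charlie": [1, 1, 1, 1],
            "delta": [0, 0, 0, 0],
        },
        ["F1", "F2", "F3", "F4"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
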