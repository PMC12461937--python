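import numpy as np
import pytest

from fimflow import features as ft
from fimflow import synthgen as sg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def focus_fixture():
    """Small sharp/blurred crop set with its feature table (shared)."""
    rng = np.random.default_rng(777)
    crops, masks, labels = sg.make_focus_pairs(150, rng)
    vectors = [
        ft.compute_features(c, m, str(i)) for i, (c, m) in enumerate(zip(crops, masks))
    ]
    return ft.feature_table(vectors), labels
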