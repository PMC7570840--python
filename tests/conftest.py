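import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def class_feature_table():
    """Feature table of 200 default-preset signals per class (session-cached)."""
    from ricetact.features import extract_feature_table
    from ricetact.signals import default_presets, generate_dataset

    ds = generate_dataset({c: 200 for c in "ABCD"}, default_presets(), n=1024, seed=11)
    return extract_feature_table(ds)
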