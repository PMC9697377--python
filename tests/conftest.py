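import numpy as np
import pytest

from maizedet.detector import PestDetector, tiny_config
from maizedet.scenes import generate_records, preset


@pytest.fixture(scope="session")
def easy_pairs():
    """A small batch of easy synthetic scenes shared across tests."""
    return generate_records(20, preset("easy", seed=11))


@pytest.fixture(scope="session")
def trained_easy_model(easy_pairs):
    """A briefly trained tiny detector (shared; treat as read-only)."""
    model = PestDetector(tiny_config(("blobA", "blobB"), seed=5))
    model.fit(easy_pairs, epochs=2)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
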