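import numpy as np
import pytest

from evidence_bench import build_speech_models


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def speech_models_small():
    """Desk-scale speech network pair (shorter series for fast fits)."""
    return build_speech_models(n_scans=64)
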