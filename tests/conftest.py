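import numpy as np
import pytest

import sicspread as sic


@pytest.fixture
def path3():
    return sic.generate_fixture("path", 3)


@pytest.fixture
def k5():
    return sic.generate_fixture("complete", 5)


@pytest.fixture
def ba_small():
    """Fixed small scale-free network shared across tests."""
    return sic.generate_ba(100, 3, seed=42)


@pytest.fixture
def coop_pair():
    """Two cooperating contagions (the minimal enhancement scenario)."""
    rel = [["neutral", "cooperative"], ["cooperative", "neutral"]]
    return sic.InteractionModel(M=2, relations=rel, a2=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
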