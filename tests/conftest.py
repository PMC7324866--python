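import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from eegmpm import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """30 segments (10 per regime), 1024 samples each, fixed seed."""
    return generate_dataset(SynthConfig(n_per_class=10, seed=42))


@pytest.fixture(scope="session")
def training_dataset():
    """60 segments (20 per regime) for pipeline-level tests."""
    return generate_dataset(SynthConfig(n_per_class=20, seed=7))
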