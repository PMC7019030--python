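"""Shared fixtures; makes the sibling ``oracles`` helper importable."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    """Fixed-seed generator for reproducible randomized tests."""
    return np.random.default_rng(20260925)
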