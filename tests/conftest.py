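import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from amphipep.background import build_background, load_composition
from amphipep.physchem import load_scale


@pytest.fixture(scope="session")
def scale():
    return load_scale()


@pytest.fixture(scope="session")
def composition():
    return load_composition()


@pytest.fixture(scope="session")
def backgrounds():
    """Full default background (all lengths, n=40,000); built once per session."""
    return build_background(n=40_000, seed=2020)
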