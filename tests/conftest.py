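import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lnccensus.simulate import SimulationConfig, make_minimal_fixture, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic bundle at the standard conditions."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def minimal_bundle():
    return make_minimal_fixture()


@pytest.fixture()
def minimal_dir(tmp_path):
    """The minimal fixture written to disk."""
    out = tmp_path / "minimal"
    make_minimal_fixture(out)
    return out
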