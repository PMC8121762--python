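import pytest

from gutpeptidomics import synthetic
from gutpeptidomics.atlas import Precursor


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig()


@pytest.fixture(scope="session")
def study(default_config):
    """The shipped synthetic study (seed 17), generated once per session."""
    return synthetic.generate_study(default_config)


@pytest.fixture
def toy_precursor():
    # A A K R G A S K G A K K A — covers dibasic, monobasic, trimmed and
    # nonbasic cut points in 13 residues.
    return Precursor("P1", "Toy", "mouse", "AAKRGASKGAKKA")
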