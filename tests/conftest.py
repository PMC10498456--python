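import pytest

from pseudopanel.simulate import build_locus
from pseudopanel.workflow import ScreenContext


@pytest.fixture(scope="session")
def locus():
    """Default desk-scale locus shared across the suite."""
    return build_locus(seed=1)


@pytest.fixture(scope="session")
def ctx():
    """Screen context (masked references, panels, control pool) built once."""
    return ScreenContext(locus_seed=1)
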