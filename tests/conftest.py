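import numpy as np
import pytest

from cellorigami import origami as om
from cellorigami.mechanics import default_materials


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def csk12_default_result():
    """Converged CSK12 origami run under the shipped calibrated defaults
    (shared across tests: the solve is deterministic)."""
    return om.run_variant(om.FoldConfig(variant="CSK12"))


@pytest.fixture(scope="session")
def sweep_table():
    """All four variants under the shipped calibrated defaults."""
    return om.sweep_complexity_nsk(om.FoldConfig())
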