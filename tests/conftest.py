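import numpy as np
import pytest
from hypothesis import settings

from jumpcount import ThermalContext

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def thermal300():
    """Thermal context at 300 K in kcal/mol (kT = 0.596 kcal/mol)."""
    return ThermalContext(temperature=300.0, energy_unit="kcal/mol")


@pytest.fixture
def rng():
    return np.random.default_rng(20230316)
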