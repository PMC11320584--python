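import numpy as np
import pytest

from a3pharm import binding_kinetics as bk


@pytest.fixture
def tracer():
    """Standard tracer configuration: 5 nM at Kd 5 nM with known rates."""
    return bk.default_tracer()


@pytest.fixture
def conc_grid():
    """12 competitor concentrations spanning 10 pM .. ~30 uM."""
    return np.logspace(-11, -4.5, 12)
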