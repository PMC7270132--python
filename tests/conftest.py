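import numpy as np
import pytest

from pcaqsp import default_parameters
from pcaqsp.model import STATE_NAMES, SystemState


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_state(rng, drugs=True) -> SystemState:
    """A random non-negative state: biology in [0, 3], drugs in [0, 1]."""
    values = {}
    for name in STATE_NAMES:
        if name in ("V", "anti_I", "anti_R", "anti_M", "I_CB"):
            values[name] = float(rng.uniform(0, 1)) if drugs else 0.0
        elif name == "A":
            values[name] = float(rng.uniform(0, 1))
        else:
            values[name] = float(rng.uniform(0, 3))
    return SystemState(**values)
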