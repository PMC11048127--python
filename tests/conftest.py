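import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evapcyte.circuit_model import vna_grid

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    """The default 10 001-point VNA grid (0.0001–3.0001 GHz, 0.3 MHz step)."""
    return vna_grid()
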