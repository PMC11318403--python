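import numpy as np
import pytest
from hypothesis import settings

from oxykin import PhysioConstants, SampledCurve

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def consts() -> PhysioConstants:
    return PhysioConstants()


@pytest.fixture(scope="session")
def fine_grid() -> np.ndarray:
    """Half-second grid over 10 minutes."""
    return np.linspace(0.0, 10.0, 1201)


@pytest.fixture(scope="session")
def ramp_curve(fine_grid) -> SampledCurve:
    return SampledCurve(fine_grid, 2.0 * fine_grid)


@pytest.fixture(scope="session")
def step_curve(fine_grid) -> SampledCurve:
    return SampledCurve(fine_grid, np.ones_like(fine_grid))
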