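import numpy as np
import pytest

from plantarvisc import (
    FITTED_PRONY_3,
    PAPER_HYPERELASTIC,
    HyperelasticParams,
    PronySeries,
    step_relaxation,
)
from plantarvisc.viscoelastic import default_hold_times


@pytest.fixture(scope="session")
def hp() -> HyperelasticParams:
    """Hyperelastic parameter set fitted to plantar aponeurosis tensile data."""
    return PAPER_HYPERELASTIC


@pytest.fixture(scope="session")
def ps3() -> PronySeries:
    """Fitted three-branch Prony series (short/medium/long-term processes)."""
    return FITTED_PRONY_3


@pytest.fixture(scope="session")
def ps1() -> PronySeries:
    """Fitted single-branch Prony series."""
    return PronySeries(((0.39, 6.0),))


@pytest.fixture(scope="session")
def hold_times() -> np.ndarray:
    return default_hold_times()


@pytest.fixture(scope="session")
def step_trace(hp, ps3, hold_times):
    """Noiseless ideal step-and-hold trace at 6% nominal strain."""
    return step_relaxation(hp, ps3, 0.06, hold_times)
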