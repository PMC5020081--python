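import numpy as np
import pytest

from ddm_recovery import DiffusionParams, simulate_trials


@pytest.fixture(scope="session")
def p_basic() -> DiffusionParams:
    """Basic parameter set without intertrial variabilities."""
    return DiffusionParams(a=1.0, v=2.0, t0=0.3, zr=0.5)


@pytest.fixture(scope="session")
def p_full() -> DiffusionParams:
    """Seven-parameter set with all intertrial variabilities active."""
    return DiffusionParams(a=1.2, v=1.0, t0=0.3, zr=0.5, sv=0.8, st0=0.15,
                           szr=0.3)


@pytest.fixture(scope="session")
def trials_full(p_full):
    """Moderate-size dataset from the full model (shared, read-only)."""
    return simulate_trials(p_full, 500, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
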