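import numpy as np
import pytest

from ironaccord.relaxometry import EchoTrain, FitResult, TruncationTrace
from ironaccord.synthetic_cohort import (
    AcquisitionProtocol,
    CohortSpec,
    simulate_echo_train,
)


@pytest.fixture
def protocol():
    return AcquisitionProtocol()


@pytest.fixture
def noiseless_train(protocol):
    return simulate_echo_train(1000.0, 5.0, protocol)


@pytest.fixture
def default_spec():
    return CohortSpec(seed=0)


def make_rician_train(s0, t2star, sigma, seed, protocol=None):
    protocol = protocol or AcquisitionProtocol()
    rng = np.random.default_rng(seed)
    return simulate_echo_train(s0, t2star, protocol, sigma, rng=rng)


def make_trace(r2_values, n_start=None):
    """Fabricate a TruncationTrace with given per-level R^2 values.

    Level i gets n_start - i echoes (n_start defaults so the last level has 3).
    """
    if n_start is None:
        n_start = len(r2_values) + 2
    levels = tuple(
        FitResult(1000.0, 5.0, r2, n_start - i) for i, r2 in enumerate(r2_values)
    )
    return TruncationTrace(levels)
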