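import numpy as np
import pytest

from cmapscan import (
    CMAPScan,
    MotorUnit,
    MotorUnitPool,
    ScanProtocol,
    simulate_scan,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20210630)


@pytest.fixture
def single_jump_scan():
    """500 stimuli: zero response for half, a 10 mV plateau for the rest."""
    amp = np.concatenate([np.zeros(250), np.full(250, 10.0)])
    return CMAPScan.from_amplitudes(amp)


@pytest.fixture
def uniform_ramp_scan():
    """500 amplitudes equally spaced from 0 to 10 mV."""
    return CMAPScan.from_amplitudes(np.linspace(0.0, 10.0, 500))


@pytest.fixture
def three_unit_pool():
    units = tuple(MotorUnit(1.0, t, 0.02) for t in (8.0, 10.0, 12.0))
    return MotorUnitPool(units, noise_sd=0.0)


@pytest.fixture
def three_unit_scan(three_unit_pool):
    return simulate_scan(three_unit_pool, ScanProtocol(13.5, 6.5), seed=7)


def random_scan(rng, n=200, n_units=15, noise=0.05):
    """Small random scan for property checks (helper, not a fixture)."""
    units = tuple(
        MotorUnit(float(a), float(t), 0.025)
        for a, t in zip(rng.uniform(0.1, 1.0, n_units), rng.uniform(5, 15, n_units))
    )
    pool = MotorUnitPool(units, noise_sd=noise)
    protocol = ScanProtocol(17.0, 4.0, n_stimuli=n)
    return simulate_scan(pool, protocol, seed=int(rng.integers(2**31)))
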