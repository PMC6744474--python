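import numpy as np
import pytest

from l4census.ephys import Sweep, SweepSet


def make_sweep(voltage, dt=1e-4, current=-100.0, onset=0.15, offset=0.75):
    v = np.asarray(voltage, dtype=float)
    t = np.arange(v.size) * dt
    return Sweep(time=t, voltage=v, current_pA=current, onset_s=onset, offset_s=offset)


def flat_sweep(level=-70.0, n=10001, **kw):
    return make_sweep(np.full(n, level), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def step_response_sweep():
    """Hyperpolarizing sweep: exponential approach to a -10 mV deflection, tau 20 ms."""
    dt = 1e-4
    t = np.arange(0, 1.0, dt)
    v = np.full(t.size, -70.0)
    stim = (t >= 0.15) & (t <= 0.75)
    v[stim] = -70.0 - 10.0 * (1 - np.exp(-(t[stim] - 0.15) / 0.020))
    after = t > 0.75
    v[after] = v[stim][-1] + (-70.0 - v[stim][-1]) * (1 - np.exp(-(t[after] - 0.75) / 0.020))
    return Sweep(time=t, voltage=v, current_pA=-100.0, onset_s=0.15, offset_s=0.75)


def single_sweep_set(sweep, protocol="fixed_holding"):
    return SweepSet(sweeps=(sweep,), protocol=protocol)
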