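import numpy as np
import pytest

from microsacc import ModelParams, MicrosaccadeProtocol


@pytest.fixture
def params_small():
    """A light network for fast unit tests."""
    return ModelParams(N=100)


@pytest.fixture
def params_default():
    return ModelParams()


@pytest.fixture
def protocol_short():
    """Shortest protocol the steady-state constraint allows (tau_d = 300 ms)."""
    return MicrosaccadeProtocol(t_fix=1500.0, t_post=400.0, peak_window=300.0,
                                baseline_window=400.0)


def std_time_average_oracle(R, f, tau_d, duration_s, rng):
    """Event-driven time average of a depressing synapse under Poisson input.

    Independent reference for the closed-form steady state: draws exponential
    inter-spike gaps at rate R (Hz), integrates the recovery
    S(t) = 1 - (1 - S0) exp(-t/tau_d) in closed form over each gap, and
    multiplies S by f at each spike.  Returns the time average over
    ``duration_s`` seconds.
    """
    duration = duration_s * 1000.0
    t, S, integral = 0.0, 1.0, 0.0
    while True:
        gap = rng.exponential(1000.0 / R)
        end = min(gap, duration - t)
        integral += end - (1.0 - S) * tau_d * (1.0 - np.exp(-end / tau_d))
        if t + gap >= duration:
            break
        S = 1.0 - (1.0 - S) * np.exp(-gap / tau_d)
        S *= f
        t += gap
    return integral / duration
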