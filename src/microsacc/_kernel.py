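"""Clock-driven integration kernel for the V1 layer.

The leak and the depression recovery are both exact exponentials, so the
fixed-step scheme can jump over runs of event-free steps: applying the
closed-form decay once over the whole gap is the exact solution of the
between-event dynamics, the same trajectory a step-by-step exponential
update would follow.  All LGN spikes falling inside a step are applied at
the step boundary, in ascending presynaptic index; the threshold test runs
once per step after all kicks (V can only decay between events, and the
decay target V0 is subthreshold, so crossings happen at kick times only).

The kernel is JIT-compiled with numba when available and runs as plain
Python otherwise; both paths execute the same function body.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


def _integrate_impl(
    spike_steps,      # int64[n_ev], sorted ascending (ties by neuron index)
    spike_neurons,    # int64[n_ev], presynaptic (LGN) index per event
    n_steps,          # total number of dt steps in the recording
    W,                # float64[Nv, Nl] weight matrix
    V,                # float64[Nv] membrane potentials, modified in place
    S,                # float64[Nl] synaptic strengths, modified in place
    tau_m, V0, VE, Vth, Vreset, g, f, tau_d, dt,
    s_win0, s_win1,   # ms; accumulate time-integral of S over [s_win0, s_win1)
):
    Nv = V.shape[0]
    Nl = S.shape[0]
    n_ev = spike_steps.shape[0]

    s_integral = np.zeros(Nl)
    do_s = s_win1 > s_win0

    cap = 1024
    out_t = np.empty(cap, np.float64)
    out_n = np.empty(cap, np.int64)
    m = 0

    t_prev = 0.0
    e = 0
    while e < n_ev:
        step = spike_steps[e]
        t_now = step * dt
        gap = t_now - t_prev
        if gap > 0.0:
            if do_s:
                u0 = max(t_prev, s_win0)
                u1 = min(t_now, s_win1)
                if u1 > u0:
                    # integral of 1 - (1-S)exp(-(t-t_prev)/tau_d) over [u0,u1)
                    a0 = np.exp(-(u0 - t_prev) / tau_d)
                    a1 = np.exp(-(u1 - t_prev) / tau_d)
                    for j in range(Nl):
                        s_integral[j] += (u1 - u0) - (1.0 - S[j]) * tau_d * (a0 - a1)
            lamV = np.exp(-gap / tau_m)
            lamS = np.exp(-gap / tau_d)
            for i in range(Nv):
                V[i] = V0 + (V[i] - V0) * lamV
            for j in range(Nl):
                S[j] = 1.0 - (1.0 - S[j]) * lamS
        while e < n_ev and spike_steps[e] == step:
            j = spike_neurons[e]
            a = g * S[j]
            for i in range(Nv):
                V[i] += a * W[i, j] * (VE - V[i])
            S[j] *= f
            e += 1
        for i in range(Nv):
            if V[i] >= Vth:
                if m == cap:
                    cap *= 2
                    tmp_t = np.empty(cap, np.float64)
                    tmp_n = np.empty(cap, np.int64)
                    tmp_t[:m] = out_t
                    tmp_n[:m] = out_n
                    out_t = tmp_t
                    out_n = tmp_n
                out_t[m] = t_now
                out_n[m] = i
                m += 1
                V[i] = Vreset
        t_prev = t_now

    t_end = n_steps * dt
    if t_end > t_prev:
        if do_s:
            u0 = max(t_prev, s_win0)
            u1 = min(t_end, s_win1)
            if u1 > u0:
                a0 = np.exp(-(u0 - t_prev) / tau_d)
                a1 = np.exp(-(u1 - t_prev) / tau_d)
                for j in range(Nl):
                    s_integral[j] += (u1 - u0) - (1.0 - S[j]) * tau_d * (a0 - a1)
        lamV = np.exp(-(t_end - t_prev) / tau_m)
        lamS = np.exp(-(t_end - t_prev) / tau_d)
        for i in range(Nv):
            V[i] = V0 + (V[i] - V0) * lamV
        for j in range(Nl):
            S[j] = 1.0 - (1.0 - S[j]) * lamS

    return out_t[:m].copy(), out_n[:m].copy(), s_integral


integrate_kernel = njit(cache=False)(_integrate_impl) if _HAVE_NUMBA else _integrate_impl
# Un-jitted reference path, kept importable so tests can check the two agree.
integrate_kernel_py = _integrate_impl
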