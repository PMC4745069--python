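"""Poisson LGN spike generation and V1 integration.

A simulation is a piecewise-constant rate schedule: within each segment the
fixated-dot position (hence the Gaussian rate profile) is fixed, and a
segment boundary where the centre moves is an instantaneous microsaccade.
Membrane potentials and synaptic strengths carry across segment boundaries
without reset.

Reproducibility: one master seed expands through ``numpy.random.SeedSequence``
spawn keys ``(segment, neuron)`` into independent substreams, so changing the
number of neurons or appending schedule segments leaves unrelated streams
untouched, and an identical (params, schedule, seed) triple yields
bit-identical spike trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernel import integrate_kernel
from .model_core import (
    ModelParams,
    RateProfile,
    connection_weights,
    gaussian_rate_profile,
    layer_geometry,
)

__all__ = [
    "SpikeTrainSet",
    "SimResult",
    "generate_poisson_spikes",
    "integrate_v1",
    "run_simulation",
    "save_spike_trains",
    "load_spike_trains",
]

# per-bin spike probability above which the Bernoulli approximation to the
# Poisson process is refused
_MAX_BIN_PROB = 0.1


@dataclass(frozen=True)
class SpikeTrainSet:
    """Spike times for one layer, stored flat and sorted by time.

    ``times`` are in ms, in [0, duration); ties are ordered by neuron index.
    """

    neuron_ids: np.ndarray  # int array, parallel to times
    times: np.ndarray       # float array, nondecreasing
    n_neurons: int
    layer: str              # "LGN" or "V1"
    duration: float         # ms

    def __len__(self) -> int:
        return len(self.times)

    def spike_times(self, j: int) -> np.ndarray:
        """Ordered spike times of neuron ``j``."""
        return self.times[self.neuron_ids == j]

    def counts_per_neuron(self) -> np.ndarray:
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"layer": self.layer, "neuron_id": self.neuron_ids, "time_ms": self.times}
        )


@dataclass(frozen=True)
class SimResult:
    """One full simulation: both layers' spikes plus provenance."""

    lgn_spikes: SpikeTrainSet
    v1_spikes: SpikeTrainSet
    params: ModelParams
    seed: int
    s_average: np.ndarray | None = None  # time-averaged S_j over the requested window


def _poisson_bernoulli(p: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Step indices of a Bernoulli(p)-per-bin spike train (at most 1/bin)."""
    return np.nonzero(rng.random(n_steps) < p)[0]


def generate_poisson_spikes(
    rates: RateProfile | np.ndarray,
    t_start: float,
    t_end: float,
    dt: float,
    rng: np.random.Generator | np.random.SeedSequence,
) -> SpikeTrainSet:
    """Homogeneous Poisson spike trains on a dt grid over ``[t_start, t_end)``.

    Each bin of width ``dt`` spikes with probability ``R_j * dt`` (rates in
    Hz, dt in ms), which requires ``R_j * dt << 1``; probabilities above 0.1
    are refused with a request for a smaller ``dt``.  Spike times are the
    bin start times.

    ``rng`` may be a single Generator (one stream shared across neurons) or
    a SeedSequence, in which case each neuron draws from its own child
    stream keyed by its index.
    """
    r = rates.rates if isinstance(rates, RateProfile) else np.asarray(rates, dtype=float)
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    p = r * dt * 1e-3
    if np.any(p > _MAX_BIN_PROB):
        raise ValueError(
            f"per-bin spike probability R_j*dt exceeds {_MAX_BIN_PROB}; "
            "use a smaller dt"
        )
    n_steps = int(round((t_end - t_start) / dt))
    N = len(r)

    per_neuron_rngs: list[np.random.Generator]
    if isinstance(rng, np.random.SeedSequence):
        per_neuron_rngs = [
            np.random.default_rng(
                np.random.SeedSequence(entropy=rng.entropy, spawn_key=rng.spawn_key + (j,))
            )
            for j in range(N)
        ]
    else:
        per_neuron_rngs = [rng] * N

    ids = []
    steps = []
    for j in range(N):
        if p[j] <= 0.0:
            continue
        s = _poisson_bernoulli(p[j], n_steps, per_neuron_rngs[j])
        if len(s):
            steps.append(s)
            ids.append(np.full(len(s), j, dtype=np.int64))
    if steps:
        steps_all = np.concatenate(steps)
        ids_all = np.concatenate(ids)
        order = np.lexsort((ids_all, steps_all))
        times = t_start + steps_all[order] * dt
        ids_all = ids_all[order]
    else:
        times = np.empty(0, dtype=float)
        ids_all = np.empty(0, dtype=np.int64)
    return SpikeTrainSet(
        neuron_ids=ids_all,
        times=times,
        n_neurons=N,
        layer="LGN",
        duration=t_end - t_start,
    )


def integrate_v1(
    lgn_spikes: SpikeTrainSet,
    W: np.ndarray,
    params: ModelParams,
    *,
    S0: np.ndarray | None = None,
    V_init: np.ndarray | None = None,
    s_average_window: tuple[float, float] | None = None,
    return_state: bool = False,
):
    """Integrate the V1 layer driven by the given LGN spikes.

    Leak dynamics ``dV_i/dt = (V0 - V_i)/tau_m`` between events; each LGN
    spike of neuron ``j`` first kicks every V1 cell by
    ``g * W_ij * S_j * (VE - V_i)`` (the delta-coupling limit of a
    conductance pulse, transmitted at pre-spike strength) and then depresses
    ``S_j -> f * S_j``; strengths recover between events; a V1 cell crossing
    ``Vth`` emits a spike and resets to ``Vreset``.

    Returns the V1 ``SpikeTrainSet``; with ``s_average_window=(t0, t1)`` the
    time-averaged strengths over that window are computed as well, and with
    ``return_state=True`` the return value is
    ``(spikes, final_V, final_S, s_average_or_None)``.
    """
    if np.any(np.diff(lgn_spikes.times) < 0):
        raise ValueError("input spike times must be sorted")
    p = params
    Nv = W.shape[0]
    Nl = W.shape[1]
    if lgn_spikes.n_neurons != Nl:
        raise ValueError("weight matrix and spike set disagree on LGN size")
    steps = np.floor(lgn_spikes.times / p.dt + 0.5).astype(np.int64)
    n_steps = int(round(lgn_spikes.duration / p.dt))
    V = np.full(Nv, p.V0, dtype=float) if V_init is None else np.array(V_init, dtype=float)
    S = np.ones(Nl, dtype=float) if S0 is None else np.array(S0, dtype=float)
    w0, w1 = s_average_window if s_average_window is not None else (0.0, -1.0)
    out_t, out_n, s_int = integrate_kernel(
        steps,
        lgn_spikes.neuron_ids.astype(np.int64),
        n_steps,
        np.ascontiguousarray(W, dtype=float),
        V,
        S,
        p.tau_m, p.V0, p.VE, p.Vth, p.Vreset, p.g, p.f, p.tau_d, p.dt,
        float(w0), float(w1),
    )
    v1 = SpikeTrainSet(
        neuron_ids=out_n,
        times=out_t,
        n_neurons=Nv,
        layer="V1",
        duration=lgn_spikes.duration,
    )
    s_avg = s_int / (w1 - w0) if s_average_window is not None else None
    if return_state:
        return v1, V, S, s_avg
    return v1


def run_simulation(
    params: ModelParams,
    rate_schedule: Sequence[tuple[float, float, float]],
    seed: int,
    *,
    s_average_window: tuple[float, float] | None = None,
) -> SimResult:
    """Run the full two-layer simulation over a piecewise-constant schedule.

    ``rate_schedule`` is a sequence of ``(t_start, t_end, center)`` segments
    that must tile ``[0, duration)`` contiguously; the centre moving between
    segments is the (instantaneous) microsaccade.  Synapse and membrane
    state carry across boundaries without reset.
    """
    if not rate_schedule:
        raise ValueError("rate schedule is empty")
    sched = sorted(rate_schedule, key=lambda seg: seg[0])
    if abs(sched[0][0]) > 1e-9:
        raise ValueError("schedule must start at t = 0")
    for (a0, a1, _), (b0, _, _) in zip(sched, sched[1:]):
        if a1 <= a0:
            raise ValueError("schedule segment has nonpositive length")
        if abs(a1 - b0) > 1e-9:
            raise ValueError("schedule segments must be contiguous (no gaps/overlaps)")
    if sched[-1][1] <= sched[-1][0]:
        raise ValueError("schedule segment has nonpositive length")
    duration = sched[-1][1]

    geom = layer_geometry(params.N, params.L)
    W = connection_weights(geom, params.sigma2)
    master = np.random.SeedSequence(entropy=int(seed))

    parts = []
    for k, (t0, t1, center) in enumerate(sched):
        profile = gaussian_rate_profile(geom, center, params.A, params.sigma1)
        seg_ss = np.random.SeedSequence(entropy=master.entropy, spawn_key=(k,))
        parts.append(generate_poisson_spikes(profile, t0, t1, params.dt, seg_ss))
    ids = np.concatenate([s.neuron_ids for s in parts])
    times = np.concatenate([s.times for s in parts])
    lgn = SpikeTrainSet(
        neuron_ids=ids, times=times, n_neurons=params.N, layer="LGN", duration=duration
    )
    out = integrate_v1(
        lgn, W, params, s_average_window=s_average_window, return_state=True
    )
    v1, _, _, s_avg = out
    return SimResult(lgn_spikes=lgn, v1_spikes=v1, params=params, seed=int(seed),
                     s_average=s_avg)


def save_spike_trains(path: str | Path, *spike_sets: SpikeTrainSet) -> None:
    """Write spike trains as delimited text: layer, neuron_id, time_ms."""
    df = pd.concat([s.to_frame() for s in spike_sets], ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def load_spike_trains(path: str | Path, duration: float | None = None) -> dict[str, SpikeTrainSet]:
    """Read spike trains written by :func:`save_spike_trains`, keyed by layer."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for layer, sub in df.groupby("layer"):
        sub = sub.sort_values(["time_ms", "neuron_id"])
        times = sub["time_ms"].to_numpy(dtype=float)
        ids = sub["neuron_id"].to_numpy(dtype=np.int64)
        dur = duration if duration is not None else (float(times.max()) + 1.0 if len(times) else 0.0)
        out[str(layer)] = SpikeTrainSet(
            neuron_ids=ids,
            times=times,
            n_neurons=int(ids.max()) + 1 if len(ids) else 0,
            layer=str(layer),
            duration=dur,
        )
    return out
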