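"""Fixation-microsaccade experiment and response statistics.

The protocol fixates the dot at ``center0`` for ``t_fix`` ms — long enough
(several tau_d) for the thalamocortical synapses to reach their depressed
steady state — then displaces the input profile by ``delta_M`` in one step
and records for ``t_post`` ms more.  The population response is the total
V1 spike count in a moving time bin of width ``T``; from that trace we take

    baseline      mean count before the displacement,
    peak          maximum count after it,
    change        peak - baseline,
    effectiveness change / baseline.

Bins straddling the displacement instant contribute to neither window.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Optional

import numpy as np

from .model_core import ModelParams
from .simulator import SimResult, SpikeTrainSet, run_simulation

__all__ = [
    "MicrosaccadeProtocol",
    "ResponseTrace",
    "ResponseSummary",
    "moving_bin_count",
    "summarize_response",
    "run_fixation_microsaccade",
    "average_summaries",
    "run_average",
]


@dataclass(frozen=True)
class MicrosaccadeProtocol:
    """Timing and measurement parameters of one fixation-microsaccade run."""

    t_fix: float = 2000.0       # ms of fixation before the displacement
    t_post: float = 500.0       # ms recorded after it
    delta_M: float = 0.8        # displacement magnitude, ring units
    T: float = 50.0             # moving-bin width, ms
    bin_step: float = 1.0       # sliding step, ms
    baseline_window: float = 500.0  # ms before the displacement
    peak_window: float = 300.0      # ms after the displacement
    center0: float = 0.0        # initial fixated-dot position

    def __post_init__(self) -> None:
        for name in ("t_fix", "t_post", "T", "bin_step",
                     "baseline_window", "peak_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delta_M < 0:
            raise ValueError("delta_M must be nonnegative")

    def validate_against(self, params: ModelParams) -> None:
        if self.t_fix < 5.0 * params.tau_d:
            raise ValueError(
                "t_fix must be at least 5*tau_d so the synapses reach steady state"
            )

    def replace(self, **changes) -> "MicrosaccadeProtocol":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ResponseTrace:
    """Total V1 spike count in a moving bin of width ``T`` sliding by ``bin_step``."""

    times: np.ndarray   # bin centres, ms
    counts: np.ndarray  # total spikes per bin
    T: float
    bin_step: float
    duration: float


# sentinel for effectiveness when the baseline is zero
UNDEFINED = None


@dataclass(frozen=True)
class ResponseSummary:
    baseline: float
    peak: float
    change: float
    effectiveness: Optional[float]  # None when baseline == 0
    n_runs: int = 1
    baseline_se: Optional[float] = None
    peak_se: Optional[float] = None
    change_se: Optional[float] = None
    effectiveness_se: Optional[float] = None


def moving_bin_count(
    v1_spikes: SpikeTrainSet, T: float, bin_step: float
) -> ResponseTrace:
    """Population spike count in a centred moving window ``[t-T/2, t+T/2)``."""
    if T <= 0 or bin_step <= 0:
        raise ValueError("T and bin_step must be strictly positive")
    if T > v1_spikes.duration:
        raise ValueError("bin width T exceeds the recording duration")
    centers = np.arange(T / 2.0, v1_spikes.duration - T / 2.0 + 1e-9, bin_step)
    t = np.sort(v1_spikes.times)
    lo = np.searchsorted(t, centers - T / 2.0, side="left")
    hi = np.searchsorted(t, centers + T / 2.0, side="left")
    return ResponseTrace(
        times=centers,
        counts=(hi - lo).astype(float),
        T=T,
        bin_step=bin_step,
        duration=v1_spikes.duration,
    )


def summarize_response(
    trace: ResponseTrace,
    t_ms: float,
    baseline_window: float,
    peak_window: float,
) -> ResponseSummary:
    """Reduce a response trace to baseline/peak/change/effectiveness at ``t_ms``.

    Only bins whose whole window lies inside the baseline interval
    ``[t_ms - baseline_window, t_ms)`` or the peak interval
    ``(t_ms, t_ms + peak_window]`` are used, so no bin straddles the
    displacement.  A zero baseline yields the ``None`` sentinel for
    effectiveness.
    """
    if t_ms - baseline_window < 0 or t_ms + peak_window > trace.duration:
        raise ValueError("analysis windows do not fit inside the trace")
    half = trace.T / 2.0
    eps = 1e-9
    base_mask = (trace.times - half >= t_ms - baseline_window - eps) & (
        trace.times + half <= t_ms + eps
    )
    peak_mask = (trace.times - half >= t_ms - eps) & (
        trace.times + half <= t_ms + peak_window + eps
    )
    if not base_mask.any() or not peak_mask.any():
        raise ValueError("analysis windows contain no complete bins")
    baseline = float(trace.counts[base_mask].mean())
    peak = float(trace.counts[peak_mask].max())
    change = peak - baseline
    eff = change / baseline if baseline > 0 else UNDEFINED
    return ResponseSummary(baseline=baseline, peak=peak, change=change,
                           effectiveness=eff)


def run_fixation_microsaccade(
    params: ModelParams,
    protocol: MicrosaccadeProtocol,
    seed: int,
) -> tuple[ResponseTrace, ResponseSummary, SimResult]:
    """One seeded fixation-microsaccade run reduced to trace and summary."""
    protocol.validate_against(params)
    schedule = [
        (0.0, protocol.t_fix, protocol.center0),
        (protocol.t_fix, protocol.t_fix + protocol.t_post,
         protocol.center0 + protocol.delta_M),
    ]
    result = run_simulation(params, schedule, seed)
    trace = moving_bin_count(result.v1_spikes, protocol.T, protocol.bin_step)
    summary = summarize_response(
        trace, protocol.t_fix, protocol.baseline_window, protocol.peak_window
    )
    return trace, summary, result


def average_summaries(summaries: list[ResponseSummary]) -> ResponseSummary:
    """Run-average of per-run summaries with standard errors of the mean.

    Effectiveness is the mean of the per-run ratios; runs where it is
    undefined (zero baseline) are excluded from that mean, and the whole
    average is undefined if no run had a positive baseline.
    """
    if not summaries:
        raise ValueError("no summaries to average")
    n = len(summaries)
    base = np.array([s.baseline for s in summaries])
    peak = np.array([s.peak for s in summaries])
    change = np.array([s.change for s in summaries])
    effs = np.array([s.effectiveness for s in summaries if s.effectiveness is not None])

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return ResponseSummary(
        baseline=float(base.mean()),
        peak=float(peak.mean()),
        change=float(change.mean()),
        effectiveness=float(effs.mean()) if len(effs) else UNDEFINED,
        n_runs=n,
        baseline_se=se(base),
        peak_se=se(peak),
        change_se=se(change),
        effectiveness_se=se(effs) if len(effs) else None,
    )


def run_average(
    params: ModelParams,
    protocol: MicrosaccadeProtocol,
    n_runs: int,
    seed: int,
) -> tuple[ResponseSummary, list[ResponseSummary], ResponseTrace]:
    """Average the protocol over ``n_runs`` independent seeded runs.

    Per-run seeds are drawn from disjoint SeedSequence substreams of the
    master seed, so changing ``n_runs`` does not reshuffle earlier runs.

    Returns ``(summary, per_run_summaries, mean_trace)``.  The headline
    summary is computed from the trial-averaged response trace: the
    displacement is time-locked, so averaging traces first and then locating
    the peak estimates the transient without the upward bias a
    max-over-noisy-bins carries in every single run (per-run summaries, which
    do carry that bias, are returned alongside).  Standard errors come from
    the per-run scatter.
    """
    per_run = []
    counts = []
    mean_trace: ResponseTrace | None = None
    for r in range(n_runs):
        child = np.random.SeedSequence(entropy=int(seed), spawn_key=(r,))
        run_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        trace, summary, _ = run_fixation_microsaccade(params, protocol, run_seed)
        per_run.append(summary)
        counts.append(trace.counts)
        mean_trace = trace
    mean_trace = ResponseTrace(
        times=mean_trace.times,
        counts=np.mean(counts, axis=0),
        T=mean_trace.T,
        bin_step=mean_trace.bin_step,
        duration=mean_trace.duration,
    )
    headline = summarize_response(
        mean_trace, protocol.t_fix, protocol.baseline_window, protocol.peak_window
    )
    scatter = average_summaries(per_run)
    summary = ResponseSummary(
        baseline=headline.baseline,
        peak=headline.peak,
        change=headline.change,
        effectiveness=headline.effectiveness,
        n_runs=n_runs,
        baseline_se=scatter.baseline_se,
        peak_se=scatter.peak_se,
        change_se=scatter.change_se,
        effectiveness_se=scatter.effectiveness_se,
    )
    return summary, per_run, mean_trace
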