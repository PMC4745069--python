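"""Parameter sweeps and the fits layered on top of them.

Sweeps rerun the fixation-microsaccade protocol over a grid of one model or
protocol parameter with disjoint seed substreams per (grid point, run), and
aggregate the run-averaged response statistics.  On top of the sweeps sit
ordinary least-squares linear fits (baseline/peak versus brightness A),
log-log power-law fits (effectiveness versus sigma1 or delta_M), and a
plateau detector for the saturation of the response peak at large
microsaccade magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ModelParams
from .protocol import MicrosaccadeProtocol, ResponseSummary, run_average

__all__ = [
    "SweepResult",
    "LinearFit",
    "PowerLawFit",
    "SaturationEstimate",
    "sweep_parameter",
    "fit_linear",
    "fit_powerlaw",
    "detect_saturation",
]

_PARAM_FIELDS = {f.name for f in fields(ModelParams)}
_PROTOCOL_FIELDS = {f.name for f in fields(MicrosaccadeProtocol)}


@dataclass(frozen=True)
class SweepResult:
    """Run-averaged response statistics over a one-parameter grid."""

    name: str
    values: np.ndarray
    summaries: list[ResponseSummary]        # one run-average per grid point
    per_run: list[list[ResponseSummary]]    # raw per-run summaries
    base_params: ModelParams
    base_protocol: MicrosaccadeProtocol
    runs: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, s, runs in zip(self.values, self.summaries, self.per_run):
            effs = [r.effectiveness for r in runs if r.effectiveness is not None]
            rows.append(
                {
                    self.name: v,
                    "baseline": s.baseline,
                    "baseline_se": s.baseline_se,
                    "peak": s.peak,
                    "peak_se": s.peak_se,
                    "change": s.change,
                    "change_se": s.change_se,
                    "effectiveness": s.effectiveness,
                    "effectiveness_se": s.effectiveness_se,
                    # mean of the per-run ratios, for comparison with the
                    # trace-averaged estimator in the main columns
                    "effectiveness_per_run_mean": (
                        float(np.mean(effs)) if effs else np.nan
                    ),
                    "n_runs": s.n_runs,
                }
            )
        return pd.DataFrame(rows)

    @property
    def effectiveness(self) -> np.ndarray:
        """Run-averaged effectiveness per grid point (NaN where undefined)."""
        return np.array(
            [np.nan if s.effectiveness is None else s.effectiveness
             for s in self.summaries]
        )

    @property
    def peaks(self) -> np.ndarray:
        return np.array([s.peak for s in self.summaries])


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    log_prefactor: float  # natural log of the prefactor
    r2: float
    x_min: float
    x_max: float

    @property
    def prefactor(self) -> float:
        return float(np.exp(self.log_prefactor))


@dataclass(frozen=True)
class SaturationEstimate:
    plateau: float
    threshold: Optional[float]  # None when the peak is still rising at the end
    fraction: float
    reached: bool


def sweep_parameter(
    base_params: ModelParams,
    base_protocol: MicrosaccadeProtocol,
    name: str,
    values: Sequence[float],
    runs: int,
    seed: int,
) -> SweepResult:
    """Run the protocol ``runs`` times at each grid value of one parameter.

    ``name`` may be any ModelParams or MicrosaccadeProtocol field.  Each
    (grid point, run) pair draws its seed from its own SeedSequence
    substream of the master seed.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty value grid")
    if np.any(np.diff(values) <= 0):
        raise ValueError("grid values must be strictly increasing")
    if name not in _PARAM_FIELDS and name not in _PROTOCOL_FIELDS:
        raise ValueError(f"unknown parameter name {name!r}")

    summaries = []
    per_run_all = []
    for iv, v in enumerate(values):
        if name in _PARAM_FIELDS:
            cast = int if name == "N" else float
            params = base_params.replace(**{name: cast(v)})
            protocol = base_protocol
        else:
            params = base_params
            protocol = base_protocol.replace(**{name: float(v)})
        child = np.random.SeedSequence(entropy=int(seed), spawn_key=(iv,))
        point_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        avg, per_run, _ = run_average(params, protocol, runs, point_seed)
        summaries.append(avg)
        per_run_all.append(per_run)
    return SweepResult(
        name=name,
        values=values,
        summaries=summaries,
        per_run=per_run_all,
        base_params=base_params,
        base_protocol=base_protocol,
        runs=runs,
        seed=int(seed),
    )


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = slope*x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate x: all values equal")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue**2))


def fit_powerlaw(
    x: Sequence[float],
    y: Sequence[float],
    fit_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Least squares on (log x, log y); the slope is the power-law exponent."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        mask = (x >= lo) & (x <= hi)
        x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 points in the fit range")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lin = fit_linear(np.log(x), np.log(y))
    return PowerLawFit(
        exponent=lin.slope,
        log_prefactor=lin.intercept,
        r2=lin.r2,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def detect_saturation(
    sweep: SweepResult | tuple[np.ndarray, np.ndarray],
    plateau_fraction: float = 0.95,
    tail: int = 3,
) -> SaturationEstimate:
    """Estimate the saturation plateau and threshold of peak(delta_M).

    The plateau is the mean peak over the top ``tail`` grid points; the
    threshold is the smallest delta_M whose run-averaged peak reaches
    ``plateau_fraction`` of the plateau.  If the last grid point still sits
    below ``plateau_fraction`` of the running maximum the curve is judged
    still rising and the threshold is flagged as not reached.
    """
    if isinstance(sweep, SweepResult):
        values, peaks = sweep.values, sweep.peaks
    else:
        values, peaks = np.asarray(sweep[0], float), np.asarray(sweep[1], float)
    if len(values) < tail:
        raise ValueError("sweep shorter than the plateau tail")
    if not 0.0 < plateau_fraction <= 1.0:
        raise ValueError("plateau_fraction must lie in (0, 1]")
    plateau = float(peaks[-tail:].mean())
    # no plateau: the top tail is not internally flat (still rising), or the
    # last point has fallen below the running maximum
    tail_flat = peaks[-tail:].min() >= plateau_fraction * plateau
    if not tail_flat or peaks[-1] < plateau_fraction * peaks.max():
        return SaturationEstimate(plateau=plateau, threshold=None,
                                  fraction=plateau_fraction, reached=False)
    above = peaks >= plateau_fraction * plateau
    idx = int(np.argmax(above))
    return SaturationEstimate(
        plateau=plateau,
        threshold=float(values[idx]),
        fraction=plateau_fraction,
        reached=True,
    )
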