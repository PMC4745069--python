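"""Spatial layout, Gaussian tuning curves, and the depressing-synapse state.

The network is a two-layer feedforward ring: ``N`` LGN relay cells and ``N``
V1 cells whose receptive-field centres are spread uniformly over ``[-L, L)``,
with the stimulus profile extended periodically with period ``2L`` so the
finite network has no boundary.  A fixated dot at position ``x_c`` drives each
LGN cell ``j`` at a Poisson rate following a Gaussian tuning curve

    R_j = A * exp(-d(x_j, x_c)^2 / (2 * sigma1^2)),

where ``d`` is the wrapped (ring) distance and ``A`` is the stimulus
brightness in Hz.  Thalamocortical weights follow a second Gaussian tuning
curve of width ``sigma2`` in the wrapped centre-to-centre offset, peak
normalised to 1.

Each LGN cell's outgoing synapses share one short-term-depression variable
``S_j`` in (0, 1]: every presynaptic spike multiplies it by ``f`` (0 < f < 1)
and between spikes it relaxes back to 1 with time constant ``tau_d``
(``dS/dt = (1 - S)/tau_d``).  Under Poisson firing at rate ``R`` the process
has the exact stationary mean

    S_ss(R) = 1 / (1 + (1 - f) * R * tau_d),

because Poisson arrivals are independent of the current value of ``S``; the
same expression is the long-run time average.  This is the quantity
:func:`steady_state_strength` returns (rates in Hz, ``tau_d`` in ms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "LayerGeometry",
    "RateProfile",
    "SynapseBank",
    "wrapped_distance",
    "layer_geometry",
    "gaussian_rate_profile",
    "connection_weights",
    "std_on_spike",
    "std_decay",
    "steady_state_strength",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class ModelParams:
    """All network, neuron and synapse constants.

    Units: positions and widths are dimensionless ring coordinates, rates in
    Hz, times in ms, potentials in mV, ``g`` dimensionless.
    """

    N: int = 1000          # neurons per layer
    L: float = 10.0        # half-extent of the ring [-L, L)
    tau_m: float = 20.0    # membrane time constant, ms
    V0: float = -70.0      # leak / resting potential, mV
    VE: float = 0.0        # excitatory reversal potential, mV
    Vth: float = -55.0     # spike threshold, mV
    Vreset: float = -58.0  # post-spike reset, mV
    g: float = 0.15        # maximal synaptic conductance scale
    f: float = 0.75        # per-spike depression factor, in (0, 1)
    tau_d: float = 300.0   # depression recovery time constant, ms
    A: float = 100.0       # stimulus brightness: LGN rate amplitude, Hz
    sigma1: float = 1.5    # width of the input tuning curve G1
    sigma2: float = 1.5    # width of the weight tuning curve G2
    dt: float = 0.1        # integration time step, ms

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        for name in ("L", "tau_m", "tau_d", "dt", "sigma1", "sigma2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must lie in the open interval (0, 1)")
        if not self.Vreset < self.Vth < self.VE:
            raise ValueError("require Vreset < Vth < VE")
        if not self.V0 < self.Vth:
            raise ValueError("require V0 < Vth")
        if self.g < 0:
            raise ValueError("g must be nonnegative")
        if self.A < 0:
            raise ValueError("A must be nonnegative")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class LayerGeometry:
    """Receptive-field centres of one layer: N points on the ring [-L, L)."""

    positions: np.ndarray
    L: float

    @property
    def spacing(self) -> float:
        return 2.0 * self.L / len(self.positions)


@dataclass(frozen=True)
class RateProfile:
    """Gaussian firing-rate profile of the LGN layer around ``center``."""

    rates: np.ndarray  # Hz, one per LGN neuron
    center: float


def wrapped_distance(x, y, L: float):
    """Shortest distance between ``x`` and ``y`` on a ring of period ``2L``.

    Accepts scalars or arrays; the result lies in ``[0, L]``.
    """
    if L <= 0:
        raise ValueError("L must be strictly positive")
    d = np.abs(np.asarray(x, dtype=float) - y) % (2.0 * L)
    return np.minimum(d, 2.0 * L - d)


def layer_geometry(N: int, L: float) -> LayerGeometry:
    """Place ``N`` receptive-field centres uniformly on the ring.

    Centres sit at ``-L + k * 2L/N`` for ``k = 0..N-1``; the endpoint ``+L``
    is identified with ``-L`` by periodicity.
    """
    if N < 1:
        raise ValueError("N must be a positive integer")
    if L <= 0:
        raise ValueError("L must be strictly positive")
    positions = -L + (2.0 * L / N) * np.arange(N, dtype=float)
    return LayerGeometry(positions=positions, L=L)


def gaussian_rate_profile(
    geometry: LayerGeometry, center: float, A: float, sigma1: float, L: float | None = None
) -> RateProfile:
    """LGN rates ``R_j = A * exp(-d_j^2 / (2 sigma1^2))``, d_j wrapped."""
    if sigma1 <= 0:
        raise ValueError("sigma1 must be strictly positive")
    if A < 0:
        raise ValueError("A must be nonnegative")
    L = geometry.L if L is None else L
    d = wrapped_distance(geometry.positions, center, L)
    return RateProfile(rates=A * np.exp(-(d**2) / (2.0 * sigma1**2)), center=center)


def connection_weights(
    geometry: LayerGeometry, sigma2: float, L: float | None = None
) -> np.ndarray:
    """Thalamocortical weight matrix ``W_ij = exp(-d_ij^2 / (2 sigma2^2))``.

    ``d_ij`` is the wrapped offset between the V1 cell ``i`` and LGN cell
    ``j`` receptive-field centres (both layers share the same geometry), so
    ``W`` is a symmetric circulant band with unit diagonal.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    L = geometry.L if L is None else L
    x = geometry.positions
    d = wrapped_distance(x[:, None], x[None, :], L)
    return np.exp(-(d**2) / (2.0 * sigma2**2))


def std_on_spike(S_j, f: float):
    """Per-spike depression: the arriving spike multiplies strength by ``f``."""
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    S_j = np.asarray(S_j, dtype=float)
    if np.any(S_j <= 0.0) or np.any(S_j > 1.0):
        raise ValueError("synaptic strength must lie in (0, 1]")
    out = f * S_j
    return float(out) if out.ndim == 0 else out

def std_decay(S_j, dt_elapsed: float, tau_d: float):
    """Recovery toward 1 over ``dt_elapsed`` ms: closed form of dS/dt=(1-S)/tau_d."""
    if tau_d <= 0:
        raise ValueError("tau_d must be strictly positive")
    if np.any(np.asarray(dt_elapsed) < 0):
        raise ValueError("elapsed time must be nonnegative")
    S_j = np.asarray(S_j, dtype=float)
    out = 1.0 - (1.0 - S_j) * np.exp(-np.asarray(dt_elapsed, dtype=float) / tau_d)
    return float(out) if out.ndim == 0 else out


def steady_state_strength(R, f: float, tau_d: float):
    """Stationary mean strength of a depressing synapse under Poisson rate ``R``.

    ``R`` in Hz, ``tau_d`` in ms.  Returns 1 at R = 0 and decreases
    monotonically with R, f held fixed; equals the long-run time average of
    the event-driven process (spike: S -> f*S; between spikes S -> 1 with
    time constant tau_d).
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    if tau_d <= 0:
        raise ValueError("tau_d must be strictly positive")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("rate must be nonnegative")
    out = 1.0 / (1.0 + (1.0 - f) * R * (tau_d / 1000.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class SynapseBank:
    """Per-presynaptic-neuron depression state (one scalar per LGN cell).

    Depression is presynaptic: all outgoing connections of LGN cell ``j``
    share the single strength ``S_j``.
    """

    S: np.ndarray
    f: float
    tau_d: float

    @classmethod
    def fresh(cls, N: int, f: float, tau_d: float) -> "SynapseBank":
        return cls(S=np.ones(N, dtype=float), f=f, tau_d=tau_d)

    def on_spike(self, j: int) -> None:
        self.S[j] = std_on_spike(self.S[j], self.f)

    def decay(self, dt_elapsed: float) -> None:
        self.S = std_decay(self.S, dt_elapsed, self.tau_d)

    def steady_state(self, rates: np.ndarray) -> np.ndarray:
        return steady_state_strength(rates, self.f, self.tau_d)


def load_params(path: str | Path) -> ModelParams:
    """Read ModelParams from a flat YAML or JSON mapping.

    The dialect is chosen by suffix (``.json`` vs anything YAML-parseable);
    unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameter fields")
    known = {f.name for f in fields(ModelParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return ModelParams(**data)


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
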