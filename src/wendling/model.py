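"""Core definitions of the extended Wendling neural mass model.

The model describes a hippocampal cortical unit as four interacting neuronal
subpopulations: pyramidal cells, excitatory interneurons, slow (dendritic,
GABA_A,slow) inhibitory interneurons and fast (somatic, GABA_A,fast)
inhibitory interneurons.  Each synaptic pathway is a second-order linear
"pulse-to-voltage" filter converting a presynaptic pulse density into a
postsynaptic potential; each population converts its summed membrane
potential back to a pulse density through the sigmoid :func:`sigmoid`.

Two algebraically equivalent formulations are provided:

* the **full system** — ten first-order ODEs in the original variable
  indexing (``y0..y4`` are PSP signals, ``y5..y9`` their derivatives), with
  the EEG-like output ``y_out = y1 - y2 - y3``;
* the **reduced system** — eight ODEs obtained by merging the two slow
  inhibitory output pathways, which share the same input and the same linear
  filter and therefore differ only by the constant factor ``C4``.  In the
  reduced indexing ``y0..y3`` are PSP signals and ``y4..y7`` their
  derivatives; the output is ``y_out = y1 - C4*y2 - y3``.

Both drifts treat the external pulse density ``p(t)`` as a fixed number for
one evaluation; stochastic input is handled by the integrators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "SigmoidParameters",
    "ModelParameters",
    "FULL_DIM",
    "REDUCED_DIM",
    "sigmoid",
    "sigmoid_slope",
    "full_drift",
    "reduced_drift",
    "output_full",
    "output_reduced",
    "map_full_to_reduced",
    "map_reduced_to_full",
]

FULL_DIM = 10
REDUCED_DIM = 8


@dataclass(frozen=True)
class SigmoidParameters:
    """Wave-to-pulse sigmoid S(v) = 2*e0 / (1 + exp(r*(v0 - v))).

    Parameters
    ----------
    v0 : float
        Half-activation membrane potential (mV).
    e0 : float
        Half of the maximal population firing rate (s^-1); S saturates at 2*e0.
    r : float
        Steepness of the sigmoid (mV^-1).
    """

    v0: float = 6.0
    e0: float = 2.5
    r: float = 0.56

    def __post_init__(self) -> None:
        if not (self.e0 > 0):
            raise ValueError(f"e0 must be positive, got {self.e0}")
        if not (self.r > 0):
            raise ValueError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class ModelParameters:
    """Gains, rate constants and connectivity of the four-population model.

    Parameters
    ----------
    A, B, G : float
        Average excitatory, slow-inhibitory and fast-inhibitory synaptic
        gains (mV).  ``B`` and ``G`` are the knobs that move the model
        between background, spiking, and gamma regimes.
    a, b, g : float
        Lumped dendritic/somatic rate constants of the corresponding
        second-order synaptic filters (s^-1).
    C1..C7 : float
        Mean numbers of synaptic contacts between subpopulations
        (dimensionless).  Defaults follow the standard choice
        C1=135, C2=C7=0.8*C1, C3=C4=0.25*C1, C5=0.3*C1, C6=0.1*C1.
    sigmoid : SigmoidParameters
        Wave-to-pulse conversion parameters shared by all populations.
    input_mean, input_variance : float
        Mean m (s^-1) and variance sigma^2 of the external pulse density
        p(t) driving the pyramidal population.  The default dispersion is a
        standard deviation of 30 s^-1 (sigma^2 = 900): this is the noise
        level that reproduces the published output variances of the model,
        which are commonly quoted with the dispersion parameter "30"
        attached to an ambiguous sigma^2 notation.
    """

    A: float = 5.0
    B: float = 45.0
    G: float = 20.0
    a: float = 100.0
    b: float = 50.0
    g: float = 350.0
    C1: float = 135.0
    C2: float = 0.8 * 135.0
    C3: float = 0.25 * 135.0
    C4: float = 0.25 * 135.0
    C5: float = 0.3 * 135.0
    C6: float = 0.1 * 135.0
    C7: float = 0.8 * 135.0
    sigmoid: SigmoidParameters = field(default_factory=SigmoidParameters)
    input_mean: float = 90.0
    input_variance: float = 900.0

    def __post_init__(self) -> None:
        for name in ("A", "B", "G"):
            if getattr(self, name) < 0:
                raise ValueError(f"synaptic gain {name} must be non-negative")
        for name in ("a", "b", "g"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"rate constant {name} must be positive")
        for i in range(1, 8):
            if not (getattr(self, f"C{i}") > 0):
                raise ValueError(f"connectivity constant C{i} must be positive")
        if self.input_variance < 0:
            raise ValueError("input_variance must be non-negative")

    def with_gains(self, *, A: float | None = None, B: float | None = None,
                   G: float | None = None) -> "ModelParameters":
        """Return a copy with some synaptic gains replaced."""
        kw = {}
        if A is not None:
            kw["A"] = A
        if B is not None:
            kw["B"] = B
        if G is not None:
            kw["G"] = G
        return replace(self, **kw)


def sigmoid(v, sp: SigmoidParameters = SigmoidParameters()):
    """Population wave-to-pulse function S(v) = 2*e0/(1 + exp(r*(v0 - v))).

    Overflow-safe for arbitrarily large ``|v|`` (implemented via the logistic
    ``expit``).  Returns a firing rate in (0, 2*e0), array-valued if ``v`` is
    an array.
    """
    return 2.0 * sp.e0 * expit(sp.r * (np.asarray(v, dtype=float) - sp.v0))


def sigmoid_slope(v, sp: SigmoidParameters = SigmoidParameters()):
    """Derivative dS/dv of :func:`sigmoid` (s^-1 mV^-1).

    Uses the logistic identity S' = r * S * (2*e0 - S) / (2*e0), which is
    positive everywhere and symmetric about v0.
    """
    s = sigmoid(v, sp)
    return sp.r * s * (2.0 * sp.e0 - s) / (2.0 * sp.e0)


def _sigmoid_scalar(v: float, v0: float, e0: float, r: float) -> float:
    # math.exp overflows for arguments > ~709; the sigmoid is flat there anyway
    z = r * (v0 - v)
    if z > 700.0:
        return 0.0
    return 2.0 * e0 / (1.0 + math.exp(z))


def full_drift(state: Sequence[float], p: ModelParameters,
               input_rate: float) -> np.ndarray:
    """Deterministic drift of the ten-equation (full) system.

    ``state`` is ``(y0..y9)``; ``input_rate`` is the external pulse density
    treated as constant for this evaluation.  Components 0-4 of the result
    are the velocities ``y5..y9``; components 5-9 are the second-order
    synaptic filter dynamics of each pathway.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (FULL_DIM,):
        raise ValueError(f"full state must have {FULL_DIM} components, got {y.shape}")
    sp = p.sigmoid
    S = lambda v: _sigmoid_scalar(v, sp.v0, sp.e0, sp.r)
    a, b, g = p.a, p.b, p.g
    d = np.empty(FULL_DIM)
    d[0:5] = y[5:10]
    d[5] = p.A * a * S(y[1] - y[2] - y[3]) - 2 * a * y[5] - a * a * y[0]
    d[6] = p.A * a * (input_rate + p.C2 * S(p.C1 * y[0])) - 2 * a * y[6] - a * a * y[1]
    d[7] = p.B * b * p.C4 * S(p.C3 * y[0]) - 2 * b * y[7] - b * b * y[2]
    d[8] = p.G * g * p.C7 * S(p.C5 * y[0] - p.C6 * y[4]) - 2 * g * y[8] - g * g * y[3]
    d[9] = p.B * b * S(p.C3 * y[0]) - 2 * b * y[9] - b * b * y[4]
    return d


def reduced_drift(state: Sequence[float], p: ModelParameters,
                  input_rate: float) -> np.ndarray:
    """Deterministic drift of the eight-equation (reduced) system.

    In the reduced indexing, ``y2`` is the slow-inhibition PSP (the former
    full-system ``y4``) and feeds both the pyramidal sum (scaled by ``C4``)
    and the fast interneurons (scaled by ``C6``); the former duplicate
    filter state is gone.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (REDUCED_DIM,):
        raise ValueError(f"reduced state must have {REDUCED_DIM} components, got {y.shape}")
    sp = p.sigmoid
    S = lambda v: _sigmoid_scalar(v, sp.v0, sp.e0, sp.r)
    a, b, g = p.a, p.b, p.g
    d = np.empty(REDUCED_DIM)
    d[0:4] = y[4:8]
    d[4] = p.A * a * S(y[1] - p.C4 * y[2] - y[3]) - 2 * a * y[4] - a * a * y[0]
    d[5] = p.A * a * (input_rate + p.C2 * S(p.C1 * y[0])) - 2 * a * y[5] - a * a * y[1]
    d[6] = p.B * b * S(p.C3 * y[0]) - 2 * b * y[6] - b * b * y[2]
    d[7] = p.G * g * p.C7 * S(p.C5 * y[0] - p.C6 * y[2]) - 2 * g * y[7] - g * g * y[3]
    return d


def output_full(state) -> float | np.ndarray:
    """EEG-like model output y_out = y1 - y2 - y3 (mV).

    Accepts a single state or an array of states with the component axis last.
    """
    y = np.asarray(state, dtype=float)
    return y[..., 1] - y[..., 2] - y[..., 3]


def output_reduced(state, p: ModelParameters) -> float | np.ndarray:
    """Reduced-system output y_out = y1 - C4*y2 - y3 (mV)."""
    y = np.asarray(state, dtype=float)
    return y[..., 1] - p.C4 * y[..., 2] - y[..., 3]


def map_full_to_reduced(state: Sequence[float], p: ModelParameters,
                        tol: float = 1e-6) -> np.ndarray:
    """Project a full state onto the reduced coordinates.

    The reduction merges the two pathways driven by S(C3*y0), which on any
    trajectory from zero initial conditions satisfy ``y2 = C4*y4`` and
    ``y7 = C4*y9`` identically.  A state violating these constraints beyond
    ``tol`` is unreachable from rest and is rejected rather than silently
    projected.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (FULL_DIM,):
        raise ValueError(f"full state must have {FULL_DIM} components, got {y.shape}")
    err = max(abs(y[2] - p.C4 * y[4]), abs(y[7] - p.C4 * y[9]))
    if err > tol:
        raise ValueError(
            "full state is not consistent with the reduction "
            f"(|y2 - C4*y4| or |y7 - C4*y9| = {err:.3g} > tol={tol:.3g}); "
            "such states are unreachable from zero initial conditions"
        )
    return np.array([y[0], y[1], y[4], y[3], y[5], y[6], y[9], y[8]])


def map_reduced_to_full(state: Sequence[float], p: ModelParameters) -> np.ndarray:
    """Embed a reduced state back into the full ten-dimensional coordinates."""
    y = np.asarray(state, dtype=float)
    if y.shape != (REDUCED_DIM,):
        raise ValueError(f"reduced state must have {REDUCED_DIM} components, got {y.shape}")
    return np.array([
        y[0], y[1], p.C4 * y[2], y[3], y[2],
        y[4], y[5], p.C4 * y[6], y[7], y[6],
    ])
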