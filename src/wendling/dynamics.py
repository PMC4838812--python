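"""Equilibria, linear stability and bifurcations of the neural mass model.

The DC offset of the simulated EEG is set by the active stable equilibrium
of the deterministic system driven by the mean pulse density p.  Setting all
time derivatives to zero and eliminating the PSP states reduces the
equilibrium condition to a single scalar equation in the output voltage::

    y_out = (A/a) * (p + C2*S(C1*y0))
            - (B/b) * C4 * S(C3*y0)
            - (G/g) * C7 * S(C5*y0 - C6*y4)

with y0 = (A/a)*S(y_out) and y4 = (B/b)*S(C3*y0).  The factors A/a, B/b, G/g
are the DC gains of the second-order synaptic filters.  Roots of this
equation are located by a sign-change scan plus Brent refinement, lifted
back to the full ten-dimensional state, polished against the exact drift,
and classified by the eigenvalues of the analytic Jacobian.

Sweeping the slow inhibitory gain B traces the nullcline of Fig-style
bifurcation diagrams: as B decreases, a saddle-node collision removes two of
the three branches (birth of the spiking limit cycle) and, further down, the
lone equilibrium regains stability (death of the limit cycle).  Both events
are localized by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, root

from .model import (
    FULL_DIM,
    REDUCED_DIM,
    ModelParameters,
    full_drift,
    output_full,
    reduced_drift,
    sigmoid,
    sigmoid_slope,
)

__all__ = [
    "EquilibriumPoint",
    "BifurcationEvent",
    "BifurcationScan",
    "nullcline_roots",
    "equilibrium_from_root",
    "equilibria",
    "jacobian",
    "classify_stability",
    "nullcline_curve",
    "find_saddle_node",
    "find_stability_transition",
]

DEFAULT_BRACKET = (-20.0, 40.0)
DEFAULT_GRID = 0.01
STABILITY_TOL = 1e-6


@dataclass
class EquilibriumPoint:
    """A fixed point of the full system with its linear stability."""

    y_out: float
    state: np.ndarray  # 10 components; the velocity half is zero
    eigenvalues: np.ndarray
    stability: str  # stable | unstable | marginal

    def to_dict(self) -> dict:
        return {
            "y_out": self.y_out,
            "state": [float(v) for v in self.state],
            "eigenvalues": [[float(ev.real), float(ev.imag)]
                            for ev in self.eigenvalues],
            "stability": self.stability,
        }


@dataclass(frozen=True)
class BifurcationEvent:
    """A detected qualitative change along a parameter sweep."""

    kind: str  # saddle_node | stability_transition
    value: float
    bracket: tuple[float, float]


@dataclass
class BifurcationScan:
    """Equilibrium branches over a swept parameter plus detected events."""

    parameter: str
    values: np.ndarray
    branches: list[list[EquilibriumPoint]]
    events: list[BifurcationEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "values": [float(v) for v in self.values],
            "branches": [[eq.to_dict() for eq in br] for br in self.branches],
            "events": [{"kind": e.kind, "value": e.value,
                        "bracket": list(e.bracket)} for e in self.events],
        }


def _nullcline_residual(y_out, p: ModelParameters, pm: float):
    """F(y_out) = RHS(y_out) - y_out; equilibria are the zeros of F."""
    sp = p.sigmoid
    y0 = (p.A / p.a) * sigmoid(y_out, sp)
    y4 = (p.B / p.b) * sigmoid(p.C3 * y0, sp)
    rhs = ((p.A / p.a) * (pm + p.C2 * sigmoid(p.C1 * y0, sp))
           - (p.B / p.b) * p.C4 * sigmoid(p.C3 * y0, sp)
           - (p.G / p.g) * p.C7 * sigmoid(p.C5 * y0 - p.C6 * y4, sp))
    return rhs - y_out


def nullcline_roots(p: ModelParameters, input_mean: float | None = None,
                    bracket: tuple[float, float] = DEFAULT_BRACKET,
                    grid: float = DEFAULT_GRID) -> np.ndarray:
    """All equilibrium output voltages within ``bracket``, sorted ascending.

    Sign changes of the combined nullcline residual on a uniform grid are
    refined by Brent's method to |F| < 1e-10; roots closer than 1e-4 mV are
    merged.
    """
    if not (grid > 0):
        raise ValueError("grid step must be positive")
    lo, hi = bracket
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"invalid bracket {bracket}")
    pm = p.input_mean if input_mean is None else input_mean

    xs = np.arange(lo, hi + grid, grid)
    fs = _nullcline_residual(xs, p, pm)
    if not np.all(np.isfinite(fs)):
        raise ValueError("nullcline residual is non-finite on the bracket")

    roots = []
    for i in np.flatnonzero(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0):
        r = brentq(_nullcline_residual, xs[i], xs[i + 1], args=(p, pm),
                   xtol=1e-13, rtol=8.9e-16)
        roots.append(float(r))
    roots.extend(float(x) for x in xs[fs == 0.0])

    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 1e-4:
            merged.append(r)
    assert all(abs(_nullcline_residual(r, p, pm)) < 1e-10 for r in merged)
    return np.array(merged)


def _state_from_root(y_out_root: float, p: ModelParameters, pm: float) -> np.ndarray:
    sp = p.sigmoid
    y = np.zeros(FULL_DIM)
    y[0] = (p.A / p.a) * sigmoid(y_out_root, sp)
    y[1] = (p.A / p.a) * (pm + p.C2 * sigmoid(p.C1 * y[0], sp))
    y[2] = (p.B / p.b) * p.C4 * sigmoid(p.C3 * y[0], sp)
    y[4] = (p.B / p.b) * sigmoid(p.C3 * y[0], sp)
    y[3] = (p.G / p.g) * p.C7 * sigmoid(p.C5 * y[0] - p.C6 * y[4], sp)
    return y


def equilibrium_from_root(y_out_root: float, p: ModelParameters,
                          input_mean: float | None = None,
                          tol: float = STABILITY_TOL) -> EquilibriumPoint:
    """Lift a nullcline root to a full fixed point and classify it.

    The PSP components are obtained by back-substitution through the
    steady-state filter gains, then polished against the exact drift; the
    result satisfies |full_drift| < 1e-9 in max-norm.
    """
    pm = p.input_mean if input_mean is None else input_mean
    y = _state_from_root(y_out_root, p, pm)
    sol = root(lambda s: full_drift(s, p, pm), y,
               jac=lambda s: jacobian(p, s), method="hybr", tol=1e-13)
    y = sol.x
    resid = np.max(np.abs(full_drift(y, p, pm)))
    if resid > 1e-9:
        raise RuntimeError(
            f"equilibrium refinement did not converge (|drift|={resid:.3g})")
    eig = np.linalg.eigvals(jacobian(p, y))
    return EquilibriumPoint(
        y_out=float(output_full(y)), state=y, eigenvalues=eig,
        stability=classify_stability(eig, tol))


def equilibria(p: ModelParameters, input_mean: float | None = None,
               bracket: tuple[float, float] = DEFAULT_BRACKET,
               grid: float = DEFAULT_GRID) -> list[EquilibriumPoint]:
    """All classified equilibria of the full system for the mean drive."""
    return [equilibrium_from_root(r, p, input_mean)
            for r in nullcline_roots(p, input_mean, bracket, grid)]


def jacobian(p: ModelParameters, state: Sequence[float]) -> np.ndarray:
    """Analytic Jacobian of the drift at ``state`` (10x10 full or 8x8 reduced)."""
    y = np.asarray(state, dtype=float)
    sp = p.sigmoid
    a, b, g = p.a, p.b, p.g
    if y.shape == (FULL_DIM,):
        J = np.zeros((FULL_DIM, FULL_DIM))
        J[0:5, 5:10] = np.eye(5)
        s_pyr = p.A * a * sigmoid_slope(y[1] - y[2] - y[3], sp)
        J[5, 0] = -a * a
        J[5, 1], J[5, 2], J[5, 3] = s_pyr, -s_pyr, -s_pyr
        J[5, 5] = -2 * a
        J[6, 0] = p.A * a * p.C2 * p.C1 * sigmoid_slope(p.C1 * y[0], sp)
        J[6, 1] = -a * a
        J[6, 6] = -2 * a
        J[7, 0] = p.B * b * p.C4 * p.C3 * sigmoid_slope(p.C3 * y[0], sp)
        J[7, 2] = -b * b
        J[7, 7] = -2 * b
        s_fast = p.G * g * p.C7 * sigmoid_slope(p.C5 * y[0] - p.C6 * y[4], sp)
        J[8, 0] = s_fast * p.C5
        J[8, 4] = -s_fast * p.C6
        J[8, 3] = -g * g
        J[8, 8] = -2 * g
        J[9, 0] = p.B * b * p.C3 * sigmoid_slope(p.C3 * y[0], sp)
        J[9, 4] = -b * b
        J[9, 9] = -2 * b
        return J
    if y.shape == (REDUCED_DIM,):
        J = np.zeros((REDUCED_DIM, REDUCED_DIM))
        J[0:4, 4:8] = np.eye(4)
        s_pyr = p.A * a * sigmoid_slope(y[1] - p.C4 * y[2] - y[3], sp)
        J[4, 0] = -a * a
        J[4, 1], J[4, 2], J[4, 3] = s_pyr, -p.C4 * s_pyr, -s_pyr
        J[4, 4] = -2 * a
        J[5, 0] = p.A * a * p.C2 * p.C1 * sigmoid_slope(p.C1 * y[0], sp)
        J[5, 1] = -a * a
        J[5, 5] = -2 * a
        J[6, 0] = p.B * b * p.C3 * sigmoid_slope(p.C3 * y[0], sp)
        J[6, 2] = -b * b
        J[6, 6] = -2 * b
        s_fast = p.G * g * p.C7 * sigmoid_slope(p.C5 * y[0] - p.C6 * y[2], sp)
        J[7, 0] = s_fast * p.C5
        J[7, 2] = -s_fast * p.C6
        J[7, 3] = -g * g
        J[7, 7] = -2 * g
        return J
    raise ValueError(f"state must have {FULL_DIM} or {REDUCED_DIM} components")


def classify_stability(eigenvalues: Sequence[complex],
                       tol: float = STABILITY_TOL) -> str:
    """Label a spectrum: stable / unstable / marginal within ``tol`` of zero."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    ev = np.asarray(eigenvalues)
    if ev.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    mx = float(np.max(ev.real))
    if mx < -tol:
        return "stable"
    if mx > tol:
        return "unstable"
    return "marginal"


def nullcline_curve(p: ModelParameters, B_values: Sequence[float],
                    input_mean: float | None = None,
                    resolution: float = 0.01) -> BifurcationScan:
    """Equilibrium branches over a sweep of the slow inhibitory gain B.

    Between consecutive grid values where the root count changes, a
    saddle-node event is localized by bisection; where a lone equilibrium
    flips stability, the eigenvalue crossing is localized likewise.
    """
    Bs = np.asarray(list(B_values), dtype=float)
    if Bs.size == 0:
        raise ValueError("B_values must be non-empty")
    branches = [equilibria(p.with_gains(B=float(B)), input_mean) for B in Bs]
    events: list[BifurcationEvent] = []
    for i in range(len(Bs) - 1):
        lo, hi = sorted((float(Bs[i]), float(Bs[i + 1])))
        n0, n1 = len(branches[i]), len(branches[i + 1])
        if n0 != n1:
            ev = find_saddle_node(p, lo, hi, resolution, input_mean)
            if ev is not None:
                events.append(ev)
        elif n0 == 1 and branches[i][0].stability != branches[i + 1][0].stability:
            ev = find_stability_transition(p, lo, hi,
                                           min(resolution, 0.005), input_mean)
            if ev is not None:
                events.append(ev)
    return BifurcationScan(parameter="B", values=Bs, branches=branches,
                           events=events)


def find_saddle_node(p: ModelParameters, B_lo: float, B_hi: float,
                     resolution: float = 0.01,
                     input_mean: float | None = None) -> BifurcationEvent | None:
    """Localize the B at which the nullcline root count changes, by bisection.

    Returns the midpoint of the final bracket (width <= ``resolution``), or
    ``None`` when the count does not change over [B_lo, B_hi].
    """
    if not (B_lo < B_hi):
        raise ValueError("need B_lo < B_hi")
    if not (0 < resolution <= B_hi - B_lo):
        raise ValueError("resolution must be positive and at most the interval width")
    count = lambda B: len(nullcline_roots(p.with_gains(B=B), input_mean))
    c_lo, c_hi = count(B_lo), count(B_hi)
    if c_lo == c_hi:
        return None
    lo, hi = B_lo, B_hi
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if count(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    return BifurcationEvent(kind="saddle_node", value=0.5 * (lo + hi),
                            bracket=(lo, hi))


def _max_real_part(p: ModelParameters, B: float,
                   input_mean: float | None) -> float:
    eqs = equilibria(p.with_gains(B=B), input_mean)
    if len(eqs) != 1:
        raise ValueError(
            f"expected a unique equilibrium at B={B}, found {len(eqs)}")
    return float(np.max(eqs[0].eigenvalues.real))


def find_stability_transition(p: ModelParameters, B_lo: float, B_hi: float,
                              resolution: float = 0.005,
                              input_mean: float | None = None,
                              ) -> BifurcationEvent | None:
    """Localize where the lone equilibrium's leading eigenvalue crosses zero.

    Bisects on the sign of the maximum eigenvalue real part; returns the
    midpoint of the final bracket (width <= ``resolution``), or ``None``
    when the sign does not change over [B_lo, B_hi].
    """
    if not (B_lo < B_hi):
        raise ValueError("need B_lo < B_hi")
    if not (0 < resolution <= B_hi - B_lo):
        raise ValueError("resolution must be positive and at most the interval width")
    s_lo = _max_real_part(p, B_lo, input_mean)
    s_hi = _max_real_part(p, B_hi, input_mean)
    if np.sign(s_lo) == np.sign(s_hi):
        return None
    lo, hi = B_lo, B_hi
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if np.sign(_max_real_part(p, mid, input_mean)) == np.sign(s_lo):
            lo = mid
        else:
            hi = mid
    return BifurcationEvent(kind="stability_transition", value=0.5 * (lo + hi),
                            bracket=(lo, hi))
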