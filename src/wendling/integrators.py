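"""Fixed-step integration of the neural mass model, classical and stochastic.

The external drive ``p(t)`` is white: a fresh value every integration step.
Treating it as an ordinary (deterministic) input inside a classical
fixed-step scheme multiplies the random fluctuation by the step size ``h``,
so the output variance shrinks roughly in proportion to ``h`` instead of
converging — a documented artifact of the legacy simulation practice.  The
``euler_classical`` and ``rk4_classical`` schemes reproduce that behaviour
deliberately.

The ``euler_sde`` scheme is the corrected stochastic forward Euler
(Euler–Maruyama) update: the deterministic drift (evaluated with the mean
drive ``m``) advances by ``h`` while the noise enters the pyramidal input
equation as an increment ``A*a*sqrt(sigma^2 * h_ref * h) * r_n`` with
``r_n ~ N(0,1)``.  The reference step ``h_ref = 0.001 s`` calibrates the
noise so that at ``h = h_ref`` the stochastic and classical Euler updates
coincide exactly; at other step sizes the variance of the output is then
stable under step refinement.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .model import (
    FULL_DIM,
    REDUCED_DIM,
    ModelParameters,
    output_full,
    output_reduced,
)

__all__ = [
    "SCHEMES",
    "IntegratorConfig",
    "NoiseStream",
    "TimeSeries",
    "Phase",
    "PhaseSchedule",
    "IntegrationDivergence",
    "simulate",
    "simulate_classical",
    "simulate_sde_euler",
    "run_phase_sequence",
    "output_variance",
    "remove_dc",
]

SCHEMES = ("euler_classical", "rk4_classical", "euler_sde")
CLASSICAL_SCHEMES = ("euler_classical", "rk4_classical")


class IntegrationDivergence(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class IntegratorConfig:
    """Settings for one fixed-step integration run.

    ``reference_h`` is the noise-calibration step of the stochastic scheme
    (see module docstring); ``transient_discard`` is the leading interval
    (s) excluded from summary statistics.
    """

    scheme: str = "euler_sde"
    h: float = 1e-3
    duration: float = 10.0
    seed: int = 0
    reference_h: float = 1e-3
    record_full_state: bool = False
    transient_discard: float = 0.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if not (self.h > 0):
            raise ValueError("step size h must be positive")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        if not (self.reference_h > 0):
            raise ValueError("reference_h must be positive")
        if self.transient_discard < 0:
            raise ValueError("transient_discard must be non-negative")


@dataclass(frozen=True)
class NoiseStream:
    """Reproducible stream of standard-normal draws (PCG64 generator).

    The same seed always yields the same sequence, which is the whole
    reproducibility contract of the simulator.
    """

    seed: int

    def standard_normal(self, n: int) -> np.ndarray:
        return np.random.default_rng(self.seed).standard_normal(n)


@dataclass
class TimeSeries:
    """Uniformly sampled simulation output with provenance metadata."""

    times: np.ndarray
    y_out: np.ndarray
    states: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def h(self) -> float:
        return float(self.metadata["h"])


@dataclass(frozen=True)
class Phase:
    """One segment of a phase schedule: a (B, G) regime held for a duration."""

    label: str
    duration: float
    B: float
    G: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"phase {self.label!r}: duration must be positive")


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered sequence of gain regimes sharing all other parameters."""

    phases: tuple[Phase, ...]
    params: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ValueError("phase schedule must contain at least one phase")


def _consts(p: ModelParameters) -> tuple:
    sp = p.sigmoid
    return (p.A, p.B, p.G, p.a, p.b, p.g,
            p.C1, p.C2, p.C3, p.C4, p.C5, p.C6, p.C7,
            sp.v0, sp.e0, sp.r)


def _f_full(y, c, p_t):
    (A, B, G, a, b, g, C1, C2, C3, C4, C5, C6, C7, v0, e0, r) = c
    y0, y1, y2, y3, y4, y5, y6, y7, y8, y9 = y

    def S(v):
        z = r * (v0 - v)
        if z > 700.0:
            return 0.0
        return 2.0 * e0 / (1.0 + math.exp(z))

    return (y5, y6, y7, y8, y9,
            A * a * S(y1 - y2 - y3) - 2 * a * y5 - a * a * y0,
            A * a * (p_t + C2 * S(C1 * y0)) - 2 * a * y6 - a * a * y1,
            B * b * C4 * S(C3 * y0) - 2 * b * y7 - b * b * y2,
            G * g * C7 * S(C5 * y0 - C6 * y4) - 2 * g * y8 - g * g * y3,
            B * b * S(C3 * y0) - 2 * b * y9 - b * b * y4)


def _f_reduced(y, c, p_t):
    (A, B, G, a, b, g, C1, C2, C3, C4, C5, C6, C7, v0, e0, r) = c
    y0, y1, y2, y3, y4, y5, y6, y7 = y

    def S(v):
        z = r * (v0 - v)
        if z > 700.0:
            return 0.0
        return 2.0 * e0 / (1.0 + math.exp(z))

    return (y4, y5, y6, y7,
            A * a * S(y1 - C4 * y2 - y3) - 2 * a * y4 - a * a * y0,
            A * a * (p_t + C2 * S(C1 * y0)) - 2 * a * y5 - a * a * y1,
            B * b * S(C3 * y0) - 2 * b * y6 - b * b * y2,
            G * g * C7 * S(C5 * y0 - C6 * y2) - 2 * g * y7 - g * g * y3)


def _check_finite(out_val: float, step: int) -> None:
    if not (-1e15 < out_val < 1e15):  # catches NaN and +-inf
        raise IntegrationDivergence(
            f"state became non-finite at step {step} "
            "(reduce the step size h or check the parameters)"
        )


def _run_loop(p: ModelParameters, scheme: str, h: float, ref_h: float,
              n_steps: int, draws: np.ndarray, system: str,
              y0: Sequence[float], record_states: bool):
    c = _consts(p)
    if system == "full":
        f, dim, noise_idx, out_of = _f_full, FULL_DIM, 6, lambda y: y[1] - y[2] - y[3]
    elif system == "reduced":
        C4 = p.C4
        f, dim, noise_idx, out_of = (
            _f_reduced, REDUCED_DIM, 5, lambda y: y[1] - C4 * y[2] - y[3])
    else:
        raise ValueError(f"unknown system {system!r}")
    y = tuple(float(v) for v in y0)
    if len(y) != dim:
        raise ValueError(f"initial state must have {dim} components")

    outs = np.empty(n_steps + 1)
    outs[0] = out_of(y)
    states = np.empty((n_steps + 1, dim)) if record_states else None
    if states is not None:
        states[0] = y

    m = p.input_mean
    sd = math.sqrt(p.input_variance)

    if scheme == "euler_classical":
        for i in range(n_steps):
            p_t = m + sd * draws[i]
            k = f(y, c, p_t)
            y = tuple(yi + h * ki for yi, ki in zip(y, k))
            out = out_of(y)
            _check_finite(out, i + 1)
            outs[i + 1] = out
            if states is not None:
                states[i + 1] = y
    elif scheme == "rk4_classical":
        h2 = 0.5 * h
        h6 = h / 6.0
        for i in range(n_steps):
            # one input draw per step, held constant across the four stages
            p_t = m + sd * draws[i]
            k1 = f(y, c, p_t)
            k2 = f(tuple(yi + h2 * ki for yi, ki in zip(y, k1)), c, p_t)
            k3 = f(tuple(yi + h2 * ki for yi, ki in zip(y, k2)), c, p_t)
            k4 = f(tuple(yi + h * ki for yi, ki in zip(y, k3)), c, p_t)
            y = tuple(yi + h6 * (a1 + 2 * (a2 + a3) + a4)
                      for yi, a1, a2, a3, a4 in zip(y, k1, k2, k3, k4))
            out = out_of(y)
            _check_finite(out, i + 1)
            outs[i + 1] = out
            if states is not None:
                states[i + 1] = y
    elif scheme == "euler_sde":
        # Wiener-increment amplitude, calibrated so that h = ref_h
        # reproduces the classical Euler update exactly
        amp = p.A * p.a * math.sqrt(p.input_variance * ref_h * h)
        for i in range(n_steps):
            k = f(y, c, m)
            yl = [yi + h * ki for yi, ki in zip(y, k)]
            yl[noise_idx] += amp * draws[i]
            y = tuple(yl)
            out = out_of(y)
            _check_finite(out, i + 1)
            outs[i + 1] = out
            if states is not None:
                states[i + 1] = y
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return outs, states, y


def _n_steps(duration: float, h: float) -> int:
    n = int(round(duration / h))
    if n < 1:
        raise ValueError("duration must cover at least one step")
    if abs(n * h - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be an integer multiple of the step size h")
    return n


def simulate(p: ModelParameters, cfg: IntegratorConfig, *, system: str = "full",
             initial_state: Sequence[float] | None = None,
             noise: np.ndarray | None = None) -> TimeSeries:
    """Integrate the model and return the sampled output.

    ``system`` selects the full (10-dim) or reduced (8-dim) formulation.
    ``initial_state`` defaults to rest (all zeros).  ``noise`` overrides the
    per-step standard-normal draws (length = number of steps); by default
    they come from ``NoiseStream(cfg.seed)``.
    """
    n = _n_steps(cfg.duration, cfg.h)
    if noise is None:
        noise = NoiseStream(cfg.seed).standard_normal(n)
    elif len(noise) != n:
        raise ValueError(f"noise must provide {n} draws, got {len(noise)}")
    dim = FULL_DIM if system == "full" else REDUCED_DIM
    y0 = np.zeros(dim) if initial_state is None else np.asarray(initial_state, float)
    outs, states, _ = _run_loop(p, cfg.scheme, cfg.h, cfg.reference_h, n, noise,
                                system, y0, cfg.record_full_state)
    times = np.arange(n + 1) * cfg.h
    meta = {
        "scheme": cfg.scheme, "h": cfg.h, "seed": cfg.seed, "system": system,
        "duration": cfg.duration, "reference_h": cfg.reference_h,
        "transient_discard": cfg.transient_discard,
        "parameters": asdict(p),
    }
    return TimeSeries(times=times, y_out=outs, states=states, metadata=meta)


def simulate_classical(p: ModelParameters, cfg: IntegratorConfig,
                       **kw) -> TimeSeries:
    """Integrate with a classical scheme (step-size-dependent noise artifact)."""
    if cfg.scheme not in CLASSICAL_SCHEMES:
        raise ValueError(f"scheme must be one of {CLASSICAL_SCHEMES}, got {cfg.scheme!r}")
    return simulate(p, cfg, **kw)


def simulate_sde_euler(p: ModelParameters, cfg: IntegratorConfig,
                       **kw) -> TimeSeries:
    """Integrate with the corrected stochastic forward Euler scheme."""
    if cfg.scheme != "euler_sde":
        raise ValueError(f"scheme must be 'euler_sde', got {cfg.scheme!r}")
    return simulate(p, cfg, **kw)


def run_phase_sequence(sched: PhaseSchedule, cfg: IntegratorConfig, *,
                       system: str = "full") -> TimeSeries:
    """Simulate a sequence of (B, G) regimes with state carried across phases.

    The noise stream is continuous over the whole run.  Per-phase summary
    statistics (mean and variance of y_out, excluding the first
    ``cfg.transient_discard`` seconds of each segment) are stored in
    ``metadata['phases']``.
    """
    h = cfg.h
    steps = [_n_steps(ph.duration, h) for ph in sched.phases]
    all_draws = NoiseStream(cfg.seed).standard_normal(sum(steps))

    dim = FULL_DIM if system == "full" else REDUCED_DIM
    y = np.zeros(dim)
    t0 = 0.0
    offset = 0
    seg_times, seg_outs, seg_states = [], [], []
    summaries = []
    for ph, n in zip(sched.phases, steps):
        p = sched.params.with_gains(B=ph.B, G=ph.G)
        outs, states, y_end = _run_loop(
            p, cfg.scheme, h, cfg.reference_h, n, all_draws[offset:offset + n],
            system, y, cfg.record_full_state)
        times = t0 + np.arange(n + 1) * h
        skip = 1 if offset else 0  # boundary sample belongs to the previous phase
        seg_times.append(times[skip:])
        seg_outs.append(outs[skip:])
        if states is not None:
            seg_states.append(states[skip:])
        w = outs[min(int(round(cfg.transient_discard / h)), n):]
        summaries.append({
            "label": ph.label, "B": ph.B, "G": ph.G,
            "t_start": t0, "t_end": t0 + n * h,
            "mean": float(np.mean(w)), "variance": float(np.var(w)),
        })
        y = np.asarray(y_end)
        t0 += n * h
        offset += n

    meta = {
        "scheme": cfg.scheme, "h": h, "seed": cfg.seed, "system": system,
        "duration": t0, "reference_h": cfg.reference_h,
        "transient_discard": cfg.transient_discard,
        "parameters": asdict(sched.params),
        "phases": summaries,
    }
    return TimeSeries(
        times=np.concatenate(seg_times),
        y_out=np.concatenate(seg_outs),
        states=np.concatenate(seg_states) if seg_states else None,
        metadata=meta,
    )


def output_variance(ts: TimeSeries, discard: float = 0.0) -> float:
    """Population variance of y_out after discarding the leading transient (s)."""
    mask = ts.times >= ts.times[0] + discard
    if not mask.any():
        raise ValueError("discard leaves an empty analysis window")
    return float(np.var(ts.y_out[mask]))


def remove_dc(ts: TimeSeries, method: str = "mean_subtract",
              fc: float | None = None) -> TimeSeries:
    """Remove the DC offset from the output, as done in EEG practice.

    ``mean_subtract`` subtracts the sample mean; ``highpass`` applies a
    first-order recursive high-pass filter with cutoff ``fc`` (Hz, must lie
    below the Nyquist frequency 1/(2h)).
    """
    if method == "mean_subtract":
        y = ts.y_out - np.mean(ts.y_out)
    elif method == "highpass":
        h = ts.h
        nyquist = 0.5 / h
        if fc is None or not (0.0 < fc < nyquist):
            raise ValueError(f"highpass cutoff fc must lie in (0, {nyquist}) Hz")
        alpha = 1.0 / (1.0 + 2.0 * math.pi * fc * h)
        y = lfilter([alpha, -alpha], [1.0, -alpha], ts.y_out)
    else:
        raise ValueError(f"unknown DC-removal method {method!r}")
    meta = dict(ts.metadata)
    meta["dc_removed"] = {"method": method, "fc": fc}
    return TimeSeries(times=ts.times.copy(), y_out=np.asarray(y),
                      states=ts.states, metadata=meta)
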