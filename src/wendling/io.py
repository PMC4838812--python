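"""Readers and writers: time-series CSV, JSON reports, YAML run configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .dynamics import BifurcationScan, EquilibriumPoint
from .integrators import IntegratorConfig, Phase, PhaseSchedule, TimeSeries
from .model import ModelParameters, SigmoidParameters

__all__ = [
    "write_timeseries_csv",
    "write_metadata_json",
    "write_equilibria_json",
    "write_scan_json",
    "write_scan_csv",
    "load_phase_schedule",
    "dump_phase_schedule",
    "parameter_hash",
]

_FLOAT_FMT = "%.17g"


def write_timeseries_csv(ts: TimeSeries, path: str | Path,
                         decimate: int = 1) -> None:
    """Write ``time,y_out[,y0..yN]`` rows; ``decimate`` keeps every k-th step."""
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    cols = [ts.times[::decimate], ts.y_out[::decimate]]
    header = "time,y_out"
    if ts.states is not None:
        st = ts.states[::decimate]
        cols.extend(st[:, j] for j in range(st.shape[1]))
        header += "," + ",".join(f"y{j}" for j in range(st.shape[1]))
    np.savetxt(path, np.column_stack(cols), fmt=_FLOAT_FMT, delimiter=",",
               header=header, comments="", newline="\n")


def write_metadata_json(ts: TimeSeries, path: str | Path) -> None:
    meta = dict(ts.metadata)
    meta["parameter_hash"] = parameter_hash(meta.get("parameters", {}))
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def write_equilibria_json(points: list[EquilibriumPoint], p: ModelParameters,
                          input_mean: float, path: str | Path) -> None:
    report = {
        "parameters": asdict(p),
        "input_mean": input_mean,
        "equilibria": [eq.to_dict() for eq in points],
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_scan_json(scan: BifurcationScan, p: ModelParameters,
                    path: str | Path) -> None:
    report = {"parameters": asdict(p), "scan": scan.to_dict()}
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_scan_csv(scan: BifurcationScan, path: str | Path) -> None:
    """Branch table ``B,y_out,stability`` for plotting the nullcline."""
    lines = [f"{scan.parameter},y_out,stability"]
    for v, branch in zip(scan.values, scan.branches):
        for eq in branch:
            lines.append(f"{v:.17g},{eq.y_out:.17g},{eq.stability}")
    Path(path).write_text("\n".join(lines) + "\n")


def parameter_hash(params: dict) -> str:
    """Stable short hash of a parameter dictionary, for run provenance logs."""
    blob = json.dumps(params, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


_MODEL_KEYS = {"A", "B", "G", "a", "b", "g", "C1", "C2", "C3", "C4", "C5",
               "C6", "C7", "input_mean", "input_variance", "v0", "e0", "r"}
_PHASE_KEYS = {"label", "duration", "B", "G"}


def _model_params_from_dict(d: dict) -> ModelParameters:
    unknown = set(d) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown model parameter keys: {sorted(unknown)}")
    sig_kw = {k: float(d[k]) for k in ("v0", "e0", "r") if k in d}
    kw = {k: float(v) for k, v in d.items() if k not in ("v0", "e0", "r")}
    if sig_kw:
        kw["sigmoid"] = SigmoidParameters(**sig_kw)
    return ModelParameters(**kw)


def load_phase_schedule(path: str | Path) -> PhaseSchedule:
    """Parse a YAML phase-schedule config.

    Layout::

        model: {A: 5.0, input_mean: 90.0, ...}   # optional overrides
        phases:
          - {label: background, duration: 10.0, B: 45.0, G: 20.0}
          - ...

    Unknown keys anywhere are rejected rather than ignored.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(doc) - {"model", "phases"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    params = _model_params_from_dict(doc.get("model") or {})
    raw_phases = doc.get("phases")
    if not raw_phases:
        raise ValueError(f"{path}: config defines no phases")
    phases = []
    for i, ph in enumerate(raw_phases):
        if not isinstance(ph, dict):
            raise ValueError(f"{path}: phase {i} must be a mapping")
        unknown = set(ph) - _PHASE_KEYS
        if unknown:
            raise ValueError(f"{path}: phase {i}: unknown keys {sorted(unknown)}")
        for key in ("duration", "B", "G"):
            if key not in ph:
                raise ValueError(f"{path}: phase {i}: missing key {key!r}")
        phases.append(Phase(label=str(ph.get("label", f"phase{i + 1}")),
                            duration=float(ph["duration"]),
                            B=float(ph["B"]), G=float(ph["G"])))
    return PhaseSchedule(phases=tuple(phases), params=params)


def dump_phase_schedule(sched: PhaseSchedule, path: str | Path) -> None:
    """Serialize a schedule back to YAML (round-trips with the loader)."""
    p = sched.params
    doc = {
        "model": {
            "A": p.A, "B": p.B, "G": p.G, "a": p.a, "b": p.b, "g": p.g,
            "C1": p.C1, "C2": p.C2, "C3": p.C3, "C4": p.C4, "C5": p.C5,
            "C6": p.C6, "C7": p.C7,
            "input_mean": p.input_mean, "input_variance": p.input_variance,
            "v0": p.sigmoid.v0, "e0": p.sigmoid.e0, "r": p.sigmoid.r,
        },
        "phases": [{"label": ph.label, "duration": ph.duration,
                    "B": ph.B, "G": ph.G} for ph in sched.phases],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_phase_config_path() -> Path:
    """Path of the packaged default five-regime schedule."""
    return Path(__file__).parent / "data" / "default_phases.yaml"
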