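"""Serialization: circuit/mechanism JSON, databases, scan bundles, CSV export.

Circuits are flat JSON objects (``tau_LP``, ``theta_LP``, ``w_LP_to_PY``,
...); databases are JSON documents with a schema tag, provenance metadata
and a list of records.  Grid scans persist as a directory of raw ``.npy``
arrays with a JSON sidecar carrying the axes, grid, base circuit and a
content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .adhp import ADHPMechanism
from .ctrnn import NEURONS, CircuitParams, SimulationConfig, Trajectory

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "RunConfig",
    "circuit_to_dict",
    "circuit_from_dict",
    "mechanism_to_dict",
    "mechanism_from_dict",
    "save_circuit_db",
    "load_circuit_db",
    "save_mechanism_db",
    "load_mechanism_db",
    "save_scan",
    "load_scan",
    "write_trajectory_csv",
    "write_adhp_csv",
]


class SchemaError(ValueError):
    """Malformed, truncated, or version-mismatched artifact."""


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility envelope for a workbench run."""

    seed: int = 0
    dt: float = 0.01
    transient: float = 50.0
    record_duration: float = 50.0
    burst_threshold: float = 0.5
    integrator: str = "rk4"
    fitness_mode: str = "base"
    weight_range: tuple[float, float] = (-16.0, 16.0)
    extras: dict = field(default_factory=dict)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            dt=self.dt,
            transient=self.transient,
            record_duration=self.record_duration,
            burst_threshold=self.burst_threshold,
            integrator=self.integrator,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "weight_range" in d:
            d["weight_range"] = tuple(d["weight_range"])
        return cls(**d)


def circuit_to_dict(params: CircuitParams) -> dict:
    out = {}
    for n in NEURONS:
        out[f"tau_{n}"] = params.time_constants[n]
        out[f"theta_{n}"] = params.biases[n]
    for s in NEURONS:
        for t in NEURONS:
            out[f"w_{s}_to_{t}"] = params.weights[(s, t)]
    return out


def circuit_from_dict(d: dict) -> CircuitParams:
    try:
        return CircuitParams(
            time_constants={n: float(d[f"tau_{n}"]) for n in NEURONS},
            biases={n: float(d[f"theta_{n}"]) for n in NEURONS},
            weights={
                (s, t): float(d[f"w_{s}_to_{t}"]) for s in NEURONS for t in NEURONS
            },
        )
    except KeyError as err:
        raise SchemaError(f"circuit record missing key {err}") from err


def mechanism_to_dict(mech: ADHPMechanism) -> dict:
    return {
        "regulated": list(mech.regulated),
        "lb": dict(mech.lb),
        "delta": dict(mech.delta),
        "window": dict(mech.window),
        "tau_theta": dict(mech.tau_theta),
    }


def mechanism_from_dict(d: dict) -> ADHPMechanism:
    try:
        return ADHPMechanism(
            regulated=tuple(d["regulated"]),
            lb=d["lb"],
            delta=d["delta"],
            window=d["window"],
            tau_theta=d["tau_theta"],
        )
    except KeyError as err:
        raise SchemaError(f"mechanism record missing key {err}") from err


def _save_db(path, kind: str, records: list[dict], meta: dict | None):
    doc = {
        "schema": f"pyloricnet/{kind}",
        "version": SCHEMA_VERSION,
        "meta": meta or {},
        "records": records,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _load_db(path, kind: str) -> tuple[list[dict], dict]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path}: not valid JSON ({err})") from err
    if not isinstance(doc, dict) or doc.get("schema") != f"pyloricnet/{kind}":
        raise SchemaError(f"{path}: expected schema pyloricnet/{kind}")
    if doc.get("version") != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {doc.get('version')} != {SCHEMA_VERSION}"
        )
    return doc["records"], doc.get("meta", {})


def save_circuit_db(path, circuits, meta: dict | None = None, extras=None):
    """``circuits`` is a list of CircuitParams; ``extras`` optional per-record
    dicts (seed, fitness, ordering, ...) merged into each record."""
    records = []
    for k, c in enumerate(circuits):
        rec = circuit_to_dict(c)
        if extras:
            rec.update(extras[k])
        records.append(rec)
    _save_db(path, "circuits", records, meta)


def load_circuit_db(path) -> tuple[list[CircuitParams], list[dict], dict]:
    records, meta = _load_db(path, "circuits")
    return [circuit_from_dict(r) for r in records], records, meta


def save_mechanism_db(path, mechanisms, meta: dict | None = None, extras=None):
    records = []
    for k, m in enumerate(mechanisms):
        rec = mechanism_to_dict(m)
        if extras:
            rec.update(extras[k])
        records.append(rec)
    _save_db(path, "mechanisms", records, meta)


def load_mechanism_db(path) -> tuple[list[ADHPMechanism], list[dict], dict]:
    records, meta = _load_db(path, "mechanisms")
    return [mechanism_from_dict(r) for r in records], records, meta


_SCAN_ARRAYS = ("o_mean", "quantiles", "pyloric", "oscillatory", "period")


def _scan_hash(scan) -> str:
    h = hashlib.sha256()
    for name in _SCAN_ARRAYS:
        h.update(np.ascontiguousarray(getattr(scan, name)).tobytes())
    for g in scan.grid:
        h.update(np.ascontiguousarray(g).tobytes())
    return h.hexdigest()


def save_scan(directory, scan) -> None:
    """Persist a GridScan as raw arrays plus a JSON sidecar with a content hash."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in _SCAN_ARRAYS:
        np.save(d / f"{name}.npy", getattr(scan, name))
    for k, g in enumerate(scan.grid):
        np.save(d / f"grid_{k}.npy", g)
    sidecar = {
        "schema": "pyloricnet/scan",
        "version": SCHEMA_VERSION,
        "axes": list(scan.axes),
        "threshold": scan.threshold,
        "base_circuit": circuit_to_dict(scan.base),
        "hash": _scan_hash(scan),
    }
    (d / "scan.json").write_text(json.dumps(sidecar, indent=1))


def load_scan(directory):
    from .prediction import GridScan

    d = Path(directory)
    try:
        sidecar = json.loads((d / "scan.json").read_text())
    except (OSError, json.JSONDecodeError) as err:
        raise SchemaError(f"{d}: unreadable scan sidecar ({err})") from err
    if sidecar.get("schema") != "pyloricnet/scan" or sidecar.get("version") != SCHEMA_VERSION:
        raise SchemaError(f"{d}: bad scan schema/version")
    try:
        arrays = {name: np.load(d / f"{name}.npy") for name in _SCAN_ARRAYS}
        grid = []
        k = 0
        while (d / f"grid_{k}.npy").exists():
            grid.append(np.load(d / f"grid_{k}.npy"))
            k += 1
    except (OSError, ValueError) as err:
        raise SchemaError(f"{d}: unreadable scan arrays ({err})") from err
    scan = GridScan(
        axes=tuple(sidecar["axes"]),
        grid=tuple(grid),
        base=circuit_from_dict(sidecar["base_circuit"]),
        threshold=sidecar["threshold"],
        **arrays,
    )
    if _scan_hash(scan) != sidecar["hash"]:
        raise SchemaError(f"{d}: scan content hash mismatch")
    return scan


def write_trajectory_csv(path, trajectory: Trajectory) -> None:
    header = "time," + ",".join(f"y_{n}" for n in NEURONS) + "," + ",".join(
        f"o_{n}" for n in NEURONS
    )
    data = np.column_stack([trajectory.times, trajectory.states, trajectory.outputs])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def write_adhp_csv(path, run, pyloric_flags=None) -> None:
    header = (
        "time,"
        + ",".join(f"theta_{n}" for n in run.regulated)
        + ","
        + ",".join(f"o_{n}" for n in NEURONS)
    )
    cols = [run.times, run.biases, run.outputs]
    if pyloric_flags is not None:
        header += ",pyloric"
        cols.append(np.asarray(pyloric_flags, dtype=float)[:, None])
    data = np.column_stack(cols)
    np.savetxt(path, data, delimiter=",", header=header, comments="")
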