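"""Configuration files, run manifests, snapshots and rendered frames.

Configurations are TOML (read with stdlib ``tomllib``; written by a small
emitter since only flat tables of numbers, strings and lists are needed).
Field snapshots are HDF5; time series and reports are CSV; frames are PNG
composites in the blue (nucleus) / green (territories) / red
(heterochromatin) convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from pathlib import Path

import h5py
import numpy as np

from .geometry import NucleusGeometry
from .model import ConversionSchedule, ModelParams, interp_h
from .solver import SimulationState, SolverConfig


# ---------------------------------------------------------------------------
# TOML
# ---------------------------------------------------------------------------

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def dumps_toml(data: dict) -> str:
    """Emit a dict of flat tables as TOML (sorted keys, bit-stable)."""
    lines = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    for k in sorted(scalars):
        lines.append(f"{k} = {_toml_value(scalars[k])}")
    for section in sorted(k for k, v in data.items() if isinstance(v, dict)):
        lines.append("")
        lines.append(f"[{section}]")
        for k in sorted(data[section]):
            lines.append(f"{k} = {_toml_value(data[section][k])}")
    return "\n".join(lines) + "\n"


def loads_toml(text: str) -> dict:
    return tomllib.loads(text)


# ---------------------------------------------------------------------------
# config <-> dataclasses
# ---------------------------------------------------------------------------

def _asdict_plain(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        if v is not None:
            out[f.name] = v
    return out


def config_dict(params: ModelParams, sched: ConversionSchedule,
                geom: NucleusGeometry, cfg: SolverConfig, seed: int,
                name: str = "", arm: str = "", tier: str = "") -> dict:
    return {"run": {"name": name, "arm": arm, "tier": tier, "seed": seed},
            "params": _asdict_plain(params),
            "schedule": _asdict_plain(sched),
            "geometry": _asdict_plain(geom),
            "solver": _asdict_plain(cfg)}


def config_from_dict(data: dict):
    """Inverse of :func:`config_dict`: (params, sched, geom, cfg, seed)."""
    params = ModelParams(**data["params"])
    sc = dict(data["schedule"])
    sched = ConversionSchedule(**sc)
    geom = NucleusGeometry(**data["geometry"])
    cfg = SolverConfig(**data["solver"])
    return params, sched, geom, cfg, int(data["run"]["seed"])


def config_checksum(data: dict) -> str:
    return hashlib.sha256(dumps_toml(data).encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance of a run directory: enough to re-execute it bit-identically."""

    name: str
    arm: str
    tier: str
    seed: int
    checksum: str
    outdir: str

    def to_toml(self) -> str:
        return dumps_toml({"manifest": dataclasses.asdict(self)})

    @classmethod
    def from_toml(cls, text: str) -> "RunManifest":
        return cls(**loads_toml(text)["manifest"])


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def save_snapshot(path, state: SimulationState) -> None:
    """All fields plus grid metadata in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=state.phi, compression="gzip")
        f.create_dataset("psi", data=state.psi, compression="gzip")
        f.create_dataset("phi0", data=state.phi0, compression="gzip")
        f.attrs["t"] = state.t
        g = state.grid
        f.attrs["nx"], f.attrs["ny"] = g.nx, g.ny
        f.attrs["Lx"], f.attrs["Ly"] = g.Lx, g.Ly


def load_snapshot(path) -> SimulationState:
    from .geometry import Grid

    with h5py.File(path, "r") as f:
        grid = Grid(int(f.attrs["nx"]), int(f.attrs["ny"]),
                    float(f.attrs["Lx"]), float(f.attrs["Ly"]))
        return SimulationState(f["phi"][...], f["psi"][...], f["phi0"][...],
                               float(f.attrs["t"]), grid)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def composite_rgb(state: SimulationState) -> np.ndarray:
    """RGB composite: nucleus blue, territories green, heterochromatin red."""
    chi = np.clip(interp_h(state.phi).sum(axis=0), 0.0, 1.0)
    red = np.clip(interp_h(state.psi), 0.0, 1.0)
    blue = np.clip(1.0 - interp_h(state.phi0), 0.0, 1.0)
    rgb = np.stack([red, chi * (1.0 - red), blue * 0.5], axis=-1)
    return rgb[::-1]          # image row 0 at the top (y decreasing)


def save_frame(path, state: SimulationState) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, composite_rgb(state))


def write_report_csv(path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
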