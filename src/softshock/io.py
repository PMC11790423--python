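"""Config files, receiver tables and snapshot output.

Experiment configs are YAML mappings of :class:`ExperimentConfig`
fields. Lengths may carry ``_mm`` suffixes and pressures ``_kpa``
suffixes, converted to strict SI at load. Snapshots are written as NPZ
archives with the axis coordinates, or as legacy ASCII VTK image data
for visualisation; receiver time series go to CSV with columns
``t, v1, v2, v3``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .experiments import ExperimentConfig, ExperimentResult
from .state import StateField

__all__ = ["load_experiment_config", "save_receivers", "save_snapshot",
           "load_snapshot", "write_vtk"]

_UNIT_SUFFIXES = {"_mm": 1e-3, "_kpa": 1e3}


def _convert_units(raw: dict) -> dict:
    out = {}
    for key, val in raw.items():
        for suffix, factor in _UNIT_SUFFIXES.items():
            if key.endswith(suffix):
                key = key[: -len(suffix)]
                val = (
                    [x * factor for x in val]
                    if isinstance(val, (list, tuple))
                    else val * factor
                )
                break
        out[key] = val
    return out


def load_experiment_config(path) -> ExperimentConfig:
    """Read one experiment config from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping")
    raw = _convert_units(raw)
    for key in ("lengths", "error_window", "mesh_ladder", "receivers"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(
                tuple(p) if isinstance(p, (list, tuple)) else p for p in raw[key]
            )
    try:
        return ExperimentConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_receivers(result: ExperimentResult, directory) -> list:
    """Write one CSV per receiver; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for n, pos in enumerate(result.receivers):
        table = result.receiver_table(pos)
        path = directory / f"receiver_{n}.csv"
        np.savetxt(path, table, delimiter=",", header="t,v1,v2,v3", comments="")
        paths.append(path)
    return paths


def save_snapshot(field: StateField, path) -> None:
    """Store the interior state and grid metadata as an NPZ archive."""
    x, y, z = field.coords()
    np.savez(
        path, q=field.interior, x=x, y=y, z=z,
        spacing=np.asarray(field.spacing), origin=np.asarray(field.origin),
        n_relax=field.n_relax,
    )


def load_snapshot(path) -> StateField:
    """Rebuild a :class:`StateField` (for restart) from an NPZ snapshot."""
    with np.load(path) as data:
        q = data["q"]
        field = StateField(
            shape=q.shape[:3], spacing=tuple(data["spacing"]),
            origin=tuple(data["origin"]), n_relax=int(data["n_relax"]), ghost=2,
        )
        field.interior[...] = q
    from .state import fill_ghosts

    fill_ghosts(field)
    return field


def write_vtk(field: StateField, path, components=(9, 10, 11),
              names=("v1", "v2", "v3")) -> None:
    """Legacy ASCII VTK structured-points export of selected components."""
    nx, ny, nz = field.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsoftshock snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN " + " ".join(f"{o:g}" for o in field.origin) + "\n")
        fh.write("SPACING " + " ".join(f"{d:g}" for d in field.spacing) + "\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for comp, name in zip(components, names):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            vals = field.interior[..., comp].transpose(2, 1, 0).ravel()
            fh.write("\n".join(f"{v:.9e}" for v in vals) + "\n")
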